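"""Simulator for spike-in calibrated TCRβ sequencing experiments.

Generates every input the pipeline consumes, with the statistical structure
the method assumes:

* a multiplicative primer-efficiency model: each V×J pair's log-efficiency
  is baseline + V effect + J effect + (double-centered) interaction, so the
  expected equimolar count of template (v, j) is proportional to
  ``exp(v_effect + j_effect + interaction)``;
* negative-binomial counts around those pair means with common dispersion
  ``d`` (default 0.125, variance m + d m²);
* log-normal clone-abundance repertoires, monoclonal and 50:50 two-clone
  mixtures as special cases;
* read-depth competition between spike-ins and genomic DNA: the expected
  read share of each pool is proportional to its input mass, so raising the
  spike-in mass starves clonotypes and produces dropouts;
* barcode-bearing 200-nt ST reads and CDR3-bearing clonotype reads with a
  configurable substitution error rate, round-tripping exactly through the
  demultiplexer at error rate 0.

All randomness flows from explicit integer seeds; child generators are
split off with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demux import N_V, N_J, MergedRead, STBarcodeLibrary, template_multiindex
from .normalize import PrimerMap
from .scaling import ScalingFactorSet

#: default magnitudes of the log-efficiency effects; chosen so the
#: template-to-template spread of equimolar counts is multi-fold, the
#: qualitative regime spike-in calibration is designed for
DEFAULT_V_SD = 0.6
DEFAULT_J_SD = 0.6
DEFAULT_INTERACTION_SD = 0.2


@dataclass(frozen=True)
class BiasModel:
    """Ground-truth per-primer-pair log-efficiencies."""

    baseline: float
    v_effects: np.ndarray  # (n_v,), mean 0
    j_effects: np.ndarray  # (n_j,), mean 0
    interaction: np.ndarray  # (n_v, n_j), double-centered

    @property
    def n_v(self) -> int:
        return self.v_effects.shape[0]

    @property
    def n_j(self) -> int:
        return self.j_effects.shape[0]

    def pair_log_means(self) -> np.ndarray:
        return (
            self.baseline
            + self.v_effects[:, None]
            + self.j_effects[None, :]
            + self.interaction
        )

    def pair_means(self) -> pd.Series:
        """Unnormalized expected counts, canonical (v_index, j_index) order."""
        m = np.exp(self.pair_log_means()).ravel()
        return pd.Series(m, index=template_multiindex(self.n_v, self.n_j))

    def true_scaling_factors(self) -> ScalingFactorSet:
        m = self.pair_means()
        return ScalingFactorSet(m / m.mean(), method="true")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    ``depth`` is the expected total read count per sample (ST-only samples
    put all of it into spike-ins). ``st_mass``/``gdna_mass`` set the input
    masses whose ratio fixes the expected read share of each pool.
    ``bias_mismatch_sd`` perturbs each clone's amplification efficiency away
    from its primer pair's spike-in efficiency (0 = the method's working
    assumption holds exactly).
    """

    d: float = 0.125
    n_samples: int = 20
    depth: float = 520_000.0
    st_mass: float = 1.0
    gdna_mass: float = 0.0
    error_rate: float = 0.001
    seed: int = 0
    bias_mismatch_sd: float = 0.0

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("dispersion d must be >= 0")
        if self.st_mass < 0 or self.gdna_mass < 0:
            raise ValueError("masses must be >= 0")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_counts(rng: np.random.Generator, means: np.ndarray, d: float) -> np.ndarray:
    """NB(mean, d) draws with variance m + d m²; Poisson at d = 0."""
    means = np.asarray(means, dtype=float)
    if d == 0:
        return rng.poisson(means)
    r = 1.0 / d
    p = 1.0 / (1.0 + d * means)
    return rng.negative_binomial(r, p)


def make_bias_model(
    seed: int = 0,
    v_sd: float = DEFAULT_V_SD,
    j_sd: float = DEFAULT_J_SD,
    interaction_sd: float = DEFAULT_INTERACTION_SD,
    baseline: float = 0.0,
    n_v: int = N_V,
    n_j: int = N_J,
) -> BiasModel:
    """Draw a primer-efficiency model: iid normal effects, centered.

    Main effects are mean-centered; the interaction matrix is
    double-centered so it cannot be absorbed into the main effects.
    """
    if min(v_sd, j_sd, interaction_sd) < 0:
        raise ValueError("effect standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, v_sd, n_v)
    j = rng.normal(0.0, j_sd, n_j)
    inter = rng.normal(0.0, interaction_sd, (n_v, n_j))
    v -= v.mean()
    j -= j.mean()
    inter = inter - inter.mean(axis=1, keepdims=True) - inter.mean(axis=0, keepdims=True) + inter.mean()
    return BiasModel(baseline, v, j, inter)


def simulate_st_matrix(
    model: BiasModel, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, ScalingFactorSet]:
    """ST-only count matrix: independent NB(m_vj, d) draws per template and
    sample, pair means scaled so each sample's expected total is ``depth``.

    Returns (matrix, ground-truth scaling factors m_vj / m_•).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = model.pair_means()
    means = (m / m.sum() * config.depth).to_numpy()
    counts = _draw_counts(
        rng, np.tile(means[:, None], (1, config.n_samples)), config.d
    )
    cols = [f"S{k + 1:02d}" for k in range(config.n_samples)]
    matrix = pd.DataFrame(counts, index=m.index, columns=cols)
    return matrix, model.true_scaling_factors()


_CDR3_LENGTHS = (36, 39, 42, 45, 48, 51)


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.choice(_CDR3_LENGTHS))
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _resembles_barcode(seq: str, barcode: str) -> bool:
    import edlib

    from .demux import revcomp

    if edlib.align(barcode, seq, mode="HW", k=1)["editDistance"] >= 0:
        return True
    return edlib.align(barcode, revcomp(seq), mode="HW", k=1)["editDistance"] >= 0


def simulate_repertoire(
    n_clones: int,
    sigma: float = 1.0,
    seed: int = 0,
    n_v: int = N_V,
    n_j: int = N_J,
    exclude_barcode: str | None = None,
) -> tuple[pd.DataFrame, PrimerMap]:
    """Ground-truth repertoire: log-normal clone abundances (shape
    ``sigma``; 0 = uniform), random V/J gene assignments consistent with
    the emitted identity PrimerMap, random CDR3 sequences.

    CDR3s within one edit of ``exclude_barcode`` (default: the universal
    ST barcode, either orientation) are redrawn — the assay's barcode is
    designed to be absent from the amplified locus.
    """
    from .demux import DEFAULT_UNIVERSAL_BARCODE

    if n_clones < 1:
        raise ValueError("need at least one clone")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if exclude_barcode is None:
        exclude_barcode = DEFAULT_UNIVERSAL_BARCODE
    rng = np.random.default_rng(seed)
    abundance = rng.lognormal(0.0, sigma, n_clones) if sigma > 0 else np.ones(n_clones)
    abundance = abundance / abundance.sum()
    v_genes = [f"TRBV{v}" for v in rng.integers(1, n_v + 1, n_clones)]
    j_genes = [f"TRBJ{j}" for j in rng.integers(1, n_j + 1, n_clones)]
    seen: set = set()
    cdr3s = []
    for k in range(n_clones):
        while True:
            c = _random_cdr3(rng)
            if (c, v_genes[k], j_genes[k]) in seen:
                continue
            if _resembles_barcode(c, exclude_barcode):
                continue
            seen.add((c, v_genes[k], j_genes[k]))
            cdr3s.append(c)
            break
    truth = pd.DataFrame(
        {
            "clonotype_id": [f"clone{k + 1:04d}" for k in range(n_clones)],
            "cdr3_nt": cdr3s,
            "v_gene": v_genes,
            "j_gene": j_genes,
            "abundance": abundance,
        }
    )
    pmap = PrimerMap(
        v_map={f"TRBV{v}": v for v in range(1, n_v + 1)},
        j_map={f"TRBJ{j}": j for j in range(1, n_j + 1)},
        n_v=n_v,
        n_j=n_j,
    )
    return truth, pmap


def two_clone_mixture(seed: int = 0, pair_a=(1, 1), pair_b=(2, 2)) -> tuple[pd.DataFrame, PrimerMap]:
    """The 50:50 two-clone validation design (transgenic-mixture analogue),
    with the clones on the given primer pairs."""
    truth, pmap = simulate_repertoire(2, sigma=0.0, seed=seed)
    truth = truth.copy()
    truth.loc[0, ["v_gene", "j_gene"]] = [f"TRBV{pair_a[0]}", f"TRBJ{pair_a[1]}"]
    truth.loc[1, ["v_gene", "j_gene"]] = [f"TRBV{pair_b[0]}", f"TRBJ{pair_b[1]}"]
    truth["abundance"] = 0.5
    return truth, pmap


def simulate_experiment(
    truth: pd.DataFrame,
    model: BiasModel,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One sample containing both spike-ins and clonotypes.

    The expected read depth splits between the pools proportionally to
    ``st_mass`` and ``gdna_mass`` (the competition effect). Each clone's
    expected count is proportional to its true abundance times its primer
    pair's relative efficiency (optionally perturbed by
    ``bias_mismatch_sd``); all counts are NB(mean, d). Clones drawn at zero
    are dropouts and are absent from the observed table.

    Returns (observed clonotype table, ST count vector).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total_mass = config.st_mass + config.gdna_mass
    if total_mass <= 0:
        raise ValueError("st_mass + gdna_mass must be > 0")
    st_share = config.st_mass / total_mass
    st_depth = config.depth * st_share
    clone_depth = config.depth * (1.0 - st_share)

    pair_means = model.pair_means()
    st_counts = pd.Series(
        np.zeros(len(pair_means), dtype=np.int64), index=pair_means.index, name="count"
    )
    if st_depth > 0:
        means = (pair_means / pair_means.sum() * st_depth).to_numpy()
        st_counts[:] = _draw_counts(rng, means, config.d)

    observed = truth.iloc[0:0].copy()
    observed["count"] = pd.Series(dtype=np.int64)
    if clone_depth > 0 and len(truth) > 0:
        rel_bias = (pair_means / pair_means.mean()).to_dict()
        v_idx = truth["v_gene"].str.replace("TRBV", "", regex=False).astype(int)
        j_idx = truth["j_gene"].str.replace("TRBJ", "", regex=False).astype(int)
        bias = np.array([rel_bias[(v, j)] for v, j in zip(v_idx, j_idx)])
        if config.bias_mismatch_sd > 0:
            bias = bias * np.exp(
                rng.normal(0.0, config.bias_mismatch_sd, len(bias))
            )
        w = truth["abundance"].to_numpy() * bias
        means = w / w.sum() * clone_depth
        counts = _draw_counts(rng, means, config.d)
        observed = truth.copy()
        observed["count"] = counts
        observed = observed.loc[observed["count"] > 0].reset_index(drop=True)
    return observed, st_counts


# ---------------------------------------------------------------------------
# read emission

ST_TEMPLATE_LENGTH = 200
_UNIVERSAL_OFFSET = 80  # where the universal barcode sits in the 200-mer
_CLONO_FLANK = 60

_ALPHABET = np.array(list("ACGT"))


def _library_fingerprint_seed(library: STBarcodeLibrary) -> int:
    blob = (library.universal_barcode + "".join(library.barcodes())).encode()
    return zlib.crc32(blob)


def st_template_sequences(library: STBarcodeLibrary) -> list[str]:
    """The 200-nt double-stranded template sequence of each ST: V-side
    filler, universal 9-mer, unique 16-mer, J-side filler. Fillers are
    drawn deterministically from the library content, so the same library
    always yields the same templates."""
    rng = np.random.default_rng(_library_fingerprint_seed(library))
    left_len = _UNIVERSAL_OFFSET
    right_len = ST_TEMPLATE_LENGTH - left_len - 9 - library.barcode_length
    v_fill = {
        v: "".join(_ALPHABET[rng.integers(0, 4, left_len)])
        for v in range(1, library.n_v + 1)
    }
    j_fill = {
        j: "".join(_ALPHABET[rng.integers(0, 4, right_len)])
        for j in range(1, library.n_j + 1)
    }
    return [
        v_fill[v] + library.universal_barcode + bc + j_fill[j]
        for (v, j, bc) in library.entries
    ]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _clonotype_read_base(
    rng: np.random.Generator, cdr3: str, library: STBarcodeLibrary
) -> str:
    """Clonotype read: random V/J flanks around the CDR3. The universal
    barcode is designed to be absent from the amplified biological locus,
    so flanks that happen to contain a near-match (within 1 edit, either
    orientation) are redrawn."""
    import edlib

    from .demux import revcomp

    ub = library.universal_barcode
    for _ in range(200):
        left = "".join(_ALPHABET[rng.integers(0, 4, _CLONO_FLANK)])
        right = "".join(_ALPHABET[rng.integers(0, 4, _CLONO_FLANK)])
        base = left + cdr3 + right
        hit_f = edlib.align(ub, base, mode="HW", k=1)["editDistance"]
        hit_r = edlib.align(ub, revcomp(base), mode="HW", k=1)["editDistance"]
        if hit_f < 0 and hit_r < 0:
            return base
    # the CDR3 itself resembles the barcode (rare): emit anyway — the reads
    # will be flagged at demux, mimicking a real assay false positive
    return base


def emit_reads(
    st_counts: pd.Series,
    observed_table: pd.DataFrame | None,
    library: STBarcodeLibrary,
    config: SimConfig,
    seed: int | None = None,
) -> list[MergedRead]:
    """One merged read per counted molecule, with substitution errors at
    ``config.error_rate``, shuffled into one stream.

    At error rate 0 the reads round-trip through the demultiplexer with
    exact count recovery.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    templates = st_template_sequences(library)
    st_counts = st_counts.reindex(
        template_multiindex(library.n_v, library.n_j), fill_value=0
    )
    reads: list[MergedRead] = []
    for idx, ((v, j), count) in enumerate(st_counts.items()):
        for n in range(int(count)):
            seq = _apply_errors(templates[idx], rng, config.error_rate)
            reads.append(MergedRead(f"ST:{v}-{j}:{n}", seq))
    if observed_table is not None and len(observed_table):
        for _, row in observed_table.iterrows():
            base = _clonotype_read_base(rng, str(row["cdr3_nt"]), library)
            for n in range(int(row["count"])):
                seq = _apply_errors(base, rng, config.error_rate)
                reads.append(MergedRead(f"CL:{row['clonotype_id']}:{n}", seq))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]
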