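"""Separate merged reads into synthetic-template (ST) and clonotype streams.

Every ST molecule carries a 9-bp *universal* barcode shared by all 260
templates and a 16-bp barcode *unique* to one V×J primer pair. A read is an
ST read iff the universal barcode occurs somewhere in it within one edit
(substitution, insertion or deletion), searched in both orientations; the
template identity is then the unique barcode matching within one edit.
Reads whose universal barcode matches but whose 16-bp barcode is missing or
ties between templates are *ambiguous* and are dropped from both streams
(they are still counted, so ST + clonotype + ambiguous = total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import edlib
import numpy as np
import pandas as pd

N_V = 20
N_J = 13
N_TEMPLATES = N_V * N_J

#: default universal 9-bp barcode used by the simulator / generated libraries
DEFAULT_UNIVERSAL_BARCODE = "ACGTCAGTC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def template_multiindex(n_v: int = N_V, n_j: int = N_J) -> pd.MultiIndex:
    """Canonical (v_index, j_index) row order: V-major, 1-based."""
    return pd.MultiIndex.from_product(
        [range(1, n_v + 1), range(1, n_j + 1)], names=["v_index", "j_index"]
    )


class MergedRead(NamedTuple):
    read_id: str
    sequence: str


class BarcodeMatch(NamedTuple):
    start: int
    end: int  # exclusive
    distance: int


@dataclass(frozen=True)
class STBarcodeLibrary:
    """The ST barcode design: one universal 9-mer plus one unique 16-mer per
    V×J primer pair.

    ``entries`` is a list of ``(v_index, j_index, unique_barcode)`` in
    canonical V-major order. Validation enforces the design invariants:
    one entry per pair, distinct barcodes, and pairwise edit distance >= 3
    so that single-edit matching can never be ambiguous within one window.
    """

    universal_barcode: str
    entries: tuple  # of (v_index, j_index, unique_barcode)
    n_v: int = N_V
    n_j: int = N_J
    min_pairwise_distance: int = 3

    def __post_init__(self):
        validate_library(self)

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][2])

    @property
    def n_templates(self) -> int:
        return self.n_v * self.n_j

    def barcodes(self) -> list[str]:
        return [e[2] for e in self.entries]

    def pair_of(self, template_index: int) -> tuple[int, int]:
        v, j, _ = self.entries[template_index]
        return (v, j)

    def index_of(self, v_index: int, j_index: int) -> int:
        return (v_index - 1) * self.n_j + (j_index - 1)


def validate_library(library: STBarcodeLibrary) -> None:
    n = library.n_v * library.n_j
    if len(library.universal_barcode) != 9:
        raise ValueError("universal barcode must be 9 nt")
    if len(library.entries) != n:
        raise ValueError(f"library must have exactly {n} entries")
    seen_pairs = set()
    barcodes = []
    length = len(library.entries[0][2])
    for k, (v, j, bc) in enumerate(library.entries):
        if not (1 <= v <= library.n_v and 1 <= j <= library.n_j):
            raise ValueError(f"entry {k}: pair ({v},{j}) out of range")
        if (v, j) in seen_pairs:
            raise ValueError(f"duplicate pair ({v},{j})")
        if len(bc) != length:
            raise ValueError("unique barcodes must share one length")
        seen_pairs.add((v, j))
        barcodes.append(bc)
    if len(set(barcodes)) != n:
        raise ValueError("unique barcodes must be distinct")
    lo = library.min_pairwise_distance
    for a in range(n):
        for b in range(a + 1, n):
            d = edlib.align(barcodes[a], barcodes[b], mode="NW", k=lo - 1)["editDistance"]
            if d >= 0:
                raise ValueError(
                    f"barcodes {a} and {b} are at edit distance {d} < {lo}"
                )


def generate_barcode_library(
    seed: int = 0,
    n_v: int = N_V,
    n_j: int = N_J,
    barcode_length: int = 16,
    universal_barcode: str = DEFAULT_UNIVERSAL_BARCODE,
    min_pairwise_distance: int = 3,
) -> STBarcodeLibrary:
    """Draw a random barcode design satisfying the library invariants.

    Rejection sampling: candidate 16-mers are kept only if their edit
    distance to every accepted barcode is >= ``min_pairwise_distance``.
    Random 16-mers are nearly always far apart, so this converges fast.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    accepted: list[str] = []
    while len(accepted) < n_v * n_j:
        cand = "".join(alphabet[rng.integers(0, 4, barcode_length)])
        ok = all(
            edlib.align(cand, bc, mode="NW", k=min_pairwise_distance - 1)["editDistance"] < 0
            for bc in accepted
        )
        if ok:
            accepted.append(cand)
    entries = tuple(
        (v, j, accepted[(v - 1) * n_j + (j - 1)])
        for v in range(1, n_v + 1)
        for j in range(1, n_j + 1)
    )
    return STBarcodeLibrary(
        universal_barcode=universal_barcode,
        entries=entries,
        n_v=n_v,
        n_j=n_j,
        min_pairwise_distance=min_pairwise_distance,
    )


def match_barcode(sequence: str, barcode: str, max_edits: int = 1) -> Optional[BarcodeMatch]:
    """Leftmost window of ``sequence`` within ``max_edits`` Levenshtein edits
    of ``barcode``, or None.

    edlib reports only optimal-distance hits, so when the best hit is not the
    leftmost *qualifying* window we rescan start offsets left of it with
    prefix-anchored (SHW) alignment.
    """
    if not sequence or not barcode:
        raise ValueError("sequence and barcode must be non-empty")
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    res = edlib.align(barcode, sequence, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    loc = min(res["locations"], key=lambda se: se[0])
    for s in range(loc[0]):
        window = sequence[s : s + len(barcode) + max_edits]
        r2 = edlib.align(barcode, window, mode="SHW", task="locations", k=max_edits)
        if r2["editDistance"] >= 0:
            end = s + r2["locations"][0][1] + 1
            return BarcodeMatch(s, end, r2["editDistance"])
    return BarcodeMatch(loc[0], loc[1] + 1, res["editDistance"])


@dataclass(frozen=True)
class Classification:
    kind: str  # "st" | "clonotype" | "ambiguous"
    template_index: Optional[int] = None  # 0-based row in canonical order
    pair: Optional[tuple[int, int]] = None
    distance: Optional[int] = None
    strand: str = "+"


#: slack (nt) around the expected unique-barcode position before falling
#: back to a full-read scan
_LOCAL_WINDOW_SLACK = 4


def _best_template(region: str, library: STBarcodeLibrary, max_edits: int):
    """Best-matching template in ``region``: (index, distance), "ambiguous",
    or None. Ties at equal distance between different templates are
    ambiguous; a strictly closer barcode wins."""
    best_d = max_edits + 1
    best: set[int] = set()
    for idx, (_, _, bc) in enumerate(library.entries):
        r = edlib.align(bc, region, mode="HW", k=min(max_edits, best_d))["editDistance"]
        if r < 0:
            continue
        if r < best_d:
            best_d, best = r, {idx}
        elif r == best_d:
            best.add(idx)
    if not best:
        return None
    if len(best) > 1:
        return "ambiguous"
    return (best.pop(), best_d)


def classify_read(
    read: MergedRead, library: STBarcodeLibrary, max_edits: int = 1
) -> Classification:
    """Classify one merged read as ST(template), clonotype, or ambiguous."""
    seq = read.sequence.upper()
    if not seq:
        raise ValueError("empty read sequence")
    strand = "+"
    m = match_barcode(seq, library.universal_barcode, max_edits)
    if m is None:
        rc = revcomp(seq)
        m = match_barcode(rc, library.universal_barcode, max_edits)
        if m is None:
            return Classification("clonotype")
        seq, strand = rc, "-"
    # the unique 16-mer sits immediately downstream of the universal barcode
    blen = library.barcode_length
    lo = max(0, m.end - _LOCAL_WINDOW_SLACK)
    hi = min(len(seq), m.end + _LOCAL_WINDOW_SLACK + blen + max_edits)
    hit = _best_template(seq[lo:hi], library, max_edits)
    if hit is None:
        hit = _best_template(seq, library, max_edits)
    if hit is None or hit == "ambiguous":
        return Classification("ambiguous", strand=strand)
    idx, dist = hit
    return Classification("st", idx, library.pair_of(idx), dist, strand)


@dataclass
class DemuxSummary:
    n_reads: int = 0
    n_st: int = 0
    n_clonotype: int = 0
    n_ambiguous: int = 0

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_st": self.n_st,
            "n_clonotype": self.n_clonotype,
            "n_ambiguous": self.n_ambiguous,
        }


def demux_sample(
    reads: Iterable[MergedRead],
    library: STBarcodeLibrary,
    max_edits: int = 1,
) -> tuple[pd.Series, list[MergedRead], DemuxSummary]:
    """Demultiplex one sample.

    Returns the per-template ST count vector (length 260, canonical
    (v_index, j_index) order), the clonotype read stream, and a summary
    whose three classes always sum to the input read count.
    """
    counts = np.zeros(library.n_templates, dtype=np.int64)
    clonotype_reads: list[MergedRead] = []
    summary = DemuxSummary()
    for read in reads:
        summary.n_reads += 1
        cls = classify_read(read, library, max_edits)
        if cls.kind == "st":
            counts[cls.template_index] += 1
            summary.n_st += 1
        elif cls.kind == "clonotype":
            clonotype_reads.append(read)
            summary.n_clonotype += 1
        else:
            summary.n_ambiguous += 1
    vec = pd.Series(
        counts, index=template_multiindex(library.n_v, library.n_j), name="count"
    )
    return vec, clonotype_reads, summary
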