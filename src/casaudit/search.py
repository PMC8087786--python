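"""Genome-wide enumeration of candidate Cas9 target sites.

For each guide the genome is scanned on both strands for 20-mers followed
by a PAM of class NGG, NAG or NGA with at most ``max_mismatches``
spacer/protospacer mismatches (default 5).  This replaces an external
Cas-OFFinder run: a mismatch-only search, no bulges, with the PAM required
to match its class exactly.

Coordinates: ``start`` is the 0-based half-open start of the full
spacer+PAM footprint on the forward strand.  Minus-strand sites report
their protospacer and PAM as read 5'->3' on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome import Genome, reverse_complement

PAM_CLASSES = ("NGG", "NAG", "NGA")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
_A, _G = _CODE["A"], _CODE["G"]
_N = _CODE["N"]

# PAM class decided by bases 2-3; the first base is unconstrained.
_PAM_SUFFIX = {"NGG": (_G, _G), "NAG": (_A, _G), "NGA": (_G, _A)}


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GuideRNA:
    """An sgRNA spacer, 5'->3', default length 20 nt."""

    id: str
    spacer: str

    def __post_init__(self):
        if not (18 <= len(self.spacer) <= 24):
            raise ValueError(f"spacer length {len(self.spacer)} outside 18-24")
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer {self.spacer!r} contains non-ACGT bases")


@dataclass(frozen=True)
class SearchParams:
    """Mismatch tolerance and enabled PAM classes.

    ``ambiguous_matches_all`` flips the handling of genomic N from the
    conservative default (N never matches and disqualifies a PAM) to
    Cas-OFFinder-style "N matches anything" in the spacer.
    """

    max_mismatches: int = 5
    pam_classes: frozenset = frozenset(PAM_CLASSES)
    ambiguous_matches_all: bool = False

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        unknown = set(self.pam_classes) - set(PAM_CLASSES)
        if unknown:
            raise ValueError(f"unknown PAM classes: {sorted(unknown)}")


@dataclass(frozen=True)
class OffTargetSite:
    """A located protospacer+PAM occurrence.

    ``start`` is the 0-based half-open start of the footprint (spacer+PAM)
    in forward-strand coordinates; ``protospacer`` and ``pam`` are read on
    the site's own strand.  ``mismatch_positions`` are 1-based positions in
    the spacer.
    """

    sgrna_id: str
    chrom: str
    start: int
    strand: str
    protospacer: str
    pam: str
    pam_class: str
    n_mismatches: int
    mismatch_positions: tuple = field(default=())

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open forward-strand interval of spacer+PAM."""
        return (self.start, self.start + len(self.protospacer) + len(self.pam))


def classify_pam(three_bases: str) -> str | None:
    """Classify a 3-base PAM as NGG / NAG / NGA, or None.

    The first base is unconstrained but any N (including in position 1)
    disqualifies the PAM under the conservative ambiguity policy.
    """
    if len(three_bases) != 3:
        raise ValueError(f"PAM must be 3 bases, got {three_bases!r}")
    if "N" in three_bases:
        return None
    suffix = three_bases[1:]
    for cls in PAM_CLASSES:
        if suffix == cls[1:]:
            return cls
    return None


def count_mismatches(
    spacer: str, protospacer: str, ambiguous_matches_all: bool = False
) -> tuple[int, tuple[int, ...]]:
    """Hamming distance between spacer and protospacer with 1-based
    mismatch positions.  Genomic N mismatches every spacer base unless
    ``ambiguous_matches_all``."""
    if len(spacer) != len(protospacer):
        raise ValueError("spacer and protospacer lengths differ")
    positions = tuple(
        i + 1
        for i, (s, p) in enumerate(zip(spacer, protospacer))
        if s != p and not (ambiguous_matches_all and p == "N")
    )
    return (len(positions), positions)


def _scan_strand(
    enc: np.ndarray, spacer_enc: np.ndarray, params: SearchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Starts (on the scanned strand) and PAM-class index of every hit."""
    L = len(spacer_enc)
    n = len(enc)
    n_windows = n - (L + 3) + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = sliding_window_view(enc, L)[:n_windows]
    diff = windows != spacer_enc
    if params.ambiguous_matches_all:
        diff &= windows != _N
    mm = diff.sum(axis=1)
    p1 = enc[L : L + n_windows]
    p2 = enc[L + 1 : L + 1 + n_windows]
    p3 = enc[L + 2 : L + 2 + n_windows]
    pam_ok = np.zeros(n_windows, dtype=bool)
    pam_cls = np.full(n_windows, -1, dtype=np.int64)
    for idx, cls in enumerate(PAM_CLASSES):
        if cls not in params.pam_classes:
            continue
        b2, b3 = _PAM_SUFFIX[cls]
        match = (p2 == b2) & (p3 == b3)
        pam_cls[match] = idx
        pam_ok |= match
    if not params.ambiguous_matches_all:
        pam_ok &= p1 != _N
    hits = pam_ok & (mm <= params.max_mismatches)
    starts = np.nonzero(hits)[0]
    return starts, pam_cls[starts]


def find_offtarget_sites(
    genome: Genome, guide: GuideRNA, params: SearchParams = SearchParams()
) -> list[OffTargetSite]:
    """All loci on both strands matching the guide under the search model.

    Perfect matches (the on-target site itself) are included; downstream
    tallies may exclude 0-mismatch sites.  Output is sorted by
    (chrom, start, strand).
    """
    spacer_enc = _encode(guide.spacer)
    L = len(guide.spacer)
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.chroms.items():
        n = len(seq)
        if n < L + 3:
            continue
        enc = _encode(seq)
        plus_starts, plus_cls = _scan_strand(enc, spacer_enc, params)
        for start, cls in zip(plus_starts.tolist(), plus_cls.tolist()):
            proto = seq[start : start + L]
            pam = seq[start + L : start + L + 3]
            n_mm, positions = count_mismatches(
                guide.spacer, proto, params.ambiguous_matches_all
            )
            sites.append(
                OffTargetSite(
                    sgrna_id=guide.id,
                    chrom=chrom,
                    start=start,
                    strand="+",
                    protospacer=proto,
                    pam=pam,
                    pam_class=PAM_CLASSES[cls],
                    n_mismatches=n_mm,
                    mismatch_positions=positions,
                )
            )
        rc = reverse_complement(seq)
        minus_starts, minus_cls = _scan_strand(_encode(rc), spacer_enc, params)
        for rc_start, cls in zip(minus_starts.tolist(), minus_cls.tolist()):
            start = n - (rc_start + L + 3)
            proto = rc[rc_start : rc_start + L]
            pam = rc[rc_start + L : rc_start + L + 3]
            n_mm, positions = count_mismatches(
                guide.spacer, proto, params.ambiguous_matches_all
            )
            sites.append(
                OffTargetSite(
                    sgrna_id=guide.id,
                    chrom=chrom,
                    start=start,
                    strand="-",
                    protospacer=proto,
                    pam=pam,
                    pam_class=PAM_CLASSES[cls],
                    n_mismatches=n_mm,
                    mismatch_positions=positions,
                )
            )
    # dedupe on (guide, chrom, start, strand) then sort
    seen: dict[tuple, OffTargetSite] = {}
    for s in sites:
        seen.setdefault((s.sgrna_id, s.chrom, s.start, s.strand), s)
    return sorted(seen.values(), key=lambda s: (s.chrom, s.start, s.strand))


def write_sites_bed(sites: list[OffTargetSite], path) -> None:
    """BED6+ export: footprint interval, guide id as name, mismatch count
    as score, then protospacer / pam / pam_class / mismatch positions."""
    with open(path, "w") as fh:
        for s in sites:
            start, end = s.footprint
            mmpos = ",".join(map(str, s.mismatch_positions)) or "."
            fh.write(
                f"{s.chrom}\t{start}\t{end}\t{s.sgrna_id}\t{s.n_mismatches}"
                f"\t{s.strand}\t{s.protospacer}\t{s.pam}\t{s.pam_class}\t{mmpos}\n"
            )
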