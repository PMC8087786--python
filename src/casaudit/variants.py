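"""Variant records, quality filtering, set algebra, typing and annotation.

The audit treats per-line variant calls as presence/absence sets keyed on
(chrom, pos, ref, alt): genotype and quality fields never enter set
comparisons.  "Core" variants are those shared by every wild-type line and
are interpreted as cultivar-vs-reference differences rather than edits;
"private" variants are those found in an edited line but in no wild-type
line, and are the raw material for off-target calling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from functools import reduce
from typing import Iterable, Iterator, Optional

import gffutils
import pysam
from intervaltree import IntervalTree

from .genome import Genome

logger = logging.getLogger(__name__)

_DNA = set("ACGT")

REGION_CATEGORIES = (
    "exonic",
    "intronic",
    "upstream",
    "downstream",
    "UTR",
    "intergenic",
)

#: Ordered ref->alt substitution keys of the 12-entry SNP spectrum.
SPECTRUM_KEYS = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


@dataclass(frozen=True)
class Variant:
    """A normalized biallelic variant call.

    ``pos`` is 1-based; the reference span is [pos, pos + len(ref) - 1]
    inclusive.  Indels use the VCF anchor-base convention (ref and alt share
    their first base).  ``dv`` is the optional count of variant-supporting
    reads carried through from the caller.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    dp: int = 0
    mq: float = 0.0
    dv: Optional[int] = None
    line_id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive reference interval covered by ref."""
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class FilterThresholds:
    """Post-calling quality filter: QUAL > 20, INFO/DP > 4, MQ > 30.

    All comparisons are strict, exactly as the thresholds are written:
    boundary values fail.
    """

    min_qual: float = 20.0
    min_dp: int = 4
    min_mq: float = 30.0

    def __post_init__(self):
        if min(self.min_qual, self.min_dp, self.min_mq) < 0:
            raise ValueError("filter thresholds must be non-negative")

    def passes(self, v: Variant) -> bool:
        return v.qual > self.min_qual and v.dp > self.min_dp and v.mq > self.min_mq


class VariantSet:
    """A collection of variants keyed on (chrom, pos, ref, alt).

    Membership ignores qual/dp/mq/dv/line_id.  Iteration order is sorted by
    key, which makes every downstream report deterministic.
    """

    def __init__(self, variants: Iterable[Variant] = (), line_id: str = ""):
        self.line_id = line_id
        self._by_key: dict[tuple, Variant] = {}
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        self._by_key[v.key] = v

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[Variant]:
        return iter(sorted(self._by_key.values(), key=lambda v: v.key))

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, Variant) else tuple(item)
        return key in self._by_key

    def __eq__(self, other) -> bool:
        return isinstance(other, VariantSet) and self.keys() == other.keys()

    def keys(self) -> set[tuple]:
        return set(self._by_key)

    def get(self, key) -> Optional[Variant]:
        return self._by_key.get(tuple(key))

    def intersection(self, other: "VariantSet") -> "VariantSet":
        keep = self.keys() & other.keys()
        return VariantSet(
            (v for k, v in self._by_key.items() if k in keep), line_id=self.line_id
        )

    def union(self, other: "VariantSet") -> "VariantSet":
        out = VariantSet(self._by_key.values(), line_id=self.line_id)
        for v in other:
            if v.key not in out._by_key:
                out.add(v)
        return out

    def difference(self, other: "VariantSet") -> "VariantSet":
        drop = other.keys()
        return VariantSet(
            (v for k, v in self._by_key.items() if k not in drop),
            line_id=self.line_id,
        )


# ---------------------------------------------------------------------------
# VCF I/O

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Root-mean-square mapping quality">
##INFO=<ID=DV,Number=1,Type=Integer,Description="Number of high-quality variant reads">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def load_variants(
    path,
    line_id: str,
    genome: Optional[Genome] = None,
) -> VariantSet:
    """Read a single-line VCF into a VariantSet.

    Multi-allelic records are split into biallelic variants.  Records with
    symbolic alleles (<DEL>, breakends) are skipped and counted.  When a
    genome is supplied every variant is left-normalized against it.
    """
    out = VariantSet(line_id=line_id)
    n_skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.alts is None:
                n_skipped += 1
                continue
            for alt in rec.alts:
                if any(c in "<>[]*." for c in alt) or not set(rec.ref) <= _DNA:
                    n_skipped += 1
                    continue
                v = Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alt=alt.upper(),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    dp=int(rec.info.get("DP", 0)),
                    mq=float(rec.info.get("MQ", 0.0)),
                    dv=(int(rec.info["DV"]) if "DV" in rec.info else None),
                    line_id=line_id,
                )
                if genome is not None:
                    v = normalize_variant(v, genome)
                    if v is None:
                        n_skipped += 1
                        continue
                out.add(v)
    if n_skipped:
        logger.info("load_variants(%s): skipped %d records", path, n_skipped)
    return out


def write_variants(vs: VariantSet, path, genome: Optional[Genome] = None) -> None:
    """Write a VariantSet as an uncompressed single-sample VCF v4.2."""
    contigs = ""
    if genome is not None:
        contigs = "".join(
            f"##contig=<ID={name},length={len(seq)}>\n"
            for name, seq in genome.chroms.items()
        )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in vs:
            info = f"DP={v.dp};MQ={v.mq:g}"
            if v.dv is not None:
                info += f";DV={v.dv}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Normalization

def normalize_variant(v: Variant, genome: Genome) -> Optional[Variant]:
    """Trim shared allele ends and left-align indels against the genome.

    Returns None for null variants (ref == alt after trimming).  Raises
    ValueError when the stated ref allele does not match the genome.
    The procedure is idempotent, so variants compared as set keys have a
    unique representation regardless of how the caller emitted them.
    """
    seq = genome.chroms.get(v.chrom)
    if seq is None:
        raise ValueError(f"unknown chromosome {v.chrom!r}")
    if seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
        raise ValueError(
            f"ref mismatch at {v.chrom}:{v.pos}: variant says {v.ref!r}, "
            f"genome has {seq[v.pos - 1 : v.pos - 1 + len(v.ref)]!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    if ref == alt:
        return None
    while True:
        # trim a shared trailing base; if an allele would empty, extend left
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                pos -= 1
                prev = seq[pos - 1]
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    if ref == alt:
        return None
    return replace(v, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Filter and set algebra

def filter_variants(vs: VariantSet, thresholds: FilterThresholds = FilterThresholds()) -> VariantSet:
    """Keep variants strictly above every quality threshold."""
    return VariantSet((v for v in vs if thresholds.passes(v)), line_id=vs.line_id)


def core_variants(wt_sets: list[VariantSet]) -> VariantSet:
    """Key-wise intersection of all wild-type sets: the cultivar variants."""
    if len(wt_sets) < 2:
        raise ValueError("core_variants needs at least two wild-type sets")
    core = reduce(lambda a, b: a.intersection(b), wt_sets)
    core.line_id = "core"
    return core


def private_variants(edited: VariantSet, wt_sets: list[VariantSet]) -> VariantSet:
    """Variants of an edited line absent from every wild-type line.

    "Absent from the wild types" means absent from the union of their sets:
    a variant seen in even a single wild-type line is not private.
    """
    if not wt_sets:
        raise ValueError("private_variants needs at least one wild-type set")
    wt_union = reduce(lambda a, b: a.union(b), wt_sets)
    return edited.difference(wt_union)


def diff_vs_core(edited: VariantSet, core: VariantSet) -> VariantSet:
    """Edited line's variants not in the shared core set."""
    return edited.difference(core)


# ---------------------------------------------------------------------------
# Typing and summaries

def classify_variant(v: Variant) -> tuple[str, int]:
    """Type a normalized variant as ('SNP', 0) / ('insertion', k) /
    ('deletion', k) / ('complex', 0)."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        return ("SNP", 0)
    if len(v.alt) > len(v.ref) and v.alt.startswith(v.ref):
        return ("insertion", len(v.alt) - len(v.ref))
    if len(v.ref) > len(v.alt) and v.ref.startswith(v.alt):
        return ("deletion", len(v.ref) - len(v.alt))
    return ("complex", 0)


def substitution_spectrum(vs: VariantSet) -> dict[str, float]:
    """Percentage of each of the 12 ref>alt substitutions among SNPs.

    Sums to 100 when the set contains at least one SNP; an all-zero table is
    returned for a SNP-free set.
    """
    counts = Counter(
        f"{v.ref}>{v.alt}" for v in vs if classify_variant(v)[0] == "SNP"
    )
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in SPECTRUM_KEYS}
    return {k: 100.0 * counts.get(k, 0) / total for k in SPECTRUM_KEYS}


def indel_length_distribution(vs: VariantSet) -> dict[int, int]:
    """Histogram of signed indel lengths (+k insertion, -k deletion)."""
    hist: Counter[int] = Counter()
    for v in vs:
        kind, length = classify_variant(v)
        if kind == "insertion":
            hist[length] += 1
        elif kind == "deletion":
            hist[-length] += 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# Region annotation

class GeneAnnotation:
    """Interval lookup over a GFF3 gene annotation.

    Categories follow the precedence exonic(CDS) > UTR > intronic >
    upstream > downstream > intergenic, with a configurable flank window
    (default 1000 bp) defining up/downstream relative to gene strand.
    """

    def __init__(self, gff_path):
        try:
            db = gffutils.create_db(
                str(gff_path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
            )
        except gffutils.exceptions.EmptyInputError as exc:
            raise ValueError("annotation contains no gene features") from exc
        self._cds: dict[str, IntervalTree] = {}
        self._utr: dict[str, IntervalTree] = {}
        self._gene: dict[str, IntervalTree] = {}
        n_genes = 0
        for gene in db.features_of_type("gene"):
            n_genes += 1
            # interval trees are half-open; features are 1-based inclusive
            self._gene.setdefault(gene.seqid, IntervalTree()).addi(
                gene.start, gene.end + 1, gene.strand
            )
        for ftype, store in (
            ("CDS", self._cds),
            ("five_prime_UTR", self._utr),
            ("three_prime_UTR", self._utr),
        ):
            for feat in db.features_of_type(ftype):
                store.setdefault(feat.seqid, IntervalTree()).addi(
                    feat.start, feat.end + 1
                )
        if n_genes == 0:
            raise ValueError("annotation contains no gene features")

    def categorize(self, chrom: str, pos: int, flank_window: int = 1000) -> str:
        if self._cds.get(chrom) and self._cds[chrom].overlaps(pos):
            return "exonic"
        if self._utr.get(chrom) and self._utr[chrom].overlaps(pos):
            return "UTR"
        genes = self._gene.get(chrom)
        if genes is None:
            return "intergenic"
        if genes.overlaps(pos):
            return "intronic"
        up = down = False
        for iv in genes.overlap(pos - flank_window, pos + flank_window + 1):
            start, end, strand = iv.begin, iv.end - 1, iv.data
            if pos < start:
                before = True
            elif pos > end:
                before = False
            else:  # pragma: no cover - overlap handled above
                continue
            if (before and strand != "-") or (not before and strand == "-"):
                up = True
            else:
                down = True
        if up:
            return "upstream"
        if down:
            return "downstream"
        return "intergenic"


def annotate_regions(
    vs: VariantSet,
    annotation: GeneAnnotation,
    flank_window: int = 1000,
) -> tuple[dict[tuple, str], dict[str, int]]:
    """Assign each variant to exactly one genomic region category.

    Returns a mapping from variant key to category and per-category counts
    that partition the set.
    """
    assigned: dict[tuple, str] = {}
    counts = {cat: 0 for cat in REGION_CATEGORIES}
    for v in vs:
        cat = annotation.categorize(v.chrom, v.pos, flank_window)
        assigned[v.key] = cat
        counts[cat] += 1
    return assigned, counts
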