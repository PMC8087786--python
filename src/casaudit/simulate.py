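"""Synthetic genomes, multi-line variant cohorts and planted CRISPR edits.

The generator emulates the statistical structure a whole-genome off-target
audit assumes: a large "cultivar" variant set shared by every regenerated
line (the transformed cultivar differs from the reference assembly), a
small per-line background of private variants (tissue-culture and somatic
noise), and planted on-/off-target edits with a machine-readable truth
table.  Defaults mirror a grapevine-style study scaled to a desk-size
genome: three wild-type lines, seven edited lines, ~0.016 shared variants
per bp and ~0.0006 private variants per bp with ~7% of shared variants
being short indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Genome
from .search import GuideRNA, OffTargetSite, SearchParams, find_offtarget_sites
from .variants import Variant, VariantSet, load_variants, normalize_variant, write_variants

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationCapacityError(RuntimeError):
    """Raised when collision-free placement fails after bounded retries."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Rates are expected variants per bp; counts per chromosome are Poisson.
    ``subthreshold_fraction`` injects records whose QUAL/DP/MQ fall below
    the default filter thresholds, to exercise the filter both ways.
    """

    genome_length: int = 50_000
    n_chromosomes: int = 1
    gc_content: float = 0.35
    n_wt_lines: int = 3
    n_edited_lines: int = 7
    shared_variant_rate: float = 0.016
    private_variant_rate: float = 0.0006
    shared_indel_fraction: float = 0.073
    subthreshold_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length < 200:
            raise ValueError("genome_length must be >= 200")
        if self.n_wt_lines < 3 or self.n_edited_lines < 1:
            raise ValueError("need >= 3 wild-type and >= 1 edited line")
        for frac in (self.gc_content, self.shared_indel_fraction,
                     self.subthreshold_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.shared_variant_rate, self.private_variant_rate) < 0:
            raise ValueError("rates must be >= 0")

    @property
    def wt_line_ids(self) -> list[str]:
        return [f"WT_{i+1}" for i in range(self.n_wt_lines)]

    @property
    def edited_line_ids(self) -> list[str]:
        return [f"ED_{i+1}" for i in range(self.n_edited_lines)]


def generate_genome(
    length: int, n_chromosomes: int = 1, gc: float = 0.5, seed: int = 0
) -> Genome:
    """Random genome with i.i.d. bases: P(G) = P(C) = gc/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = Genome()
    for i in range(n_chromosomes):
        seq = rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")
        genome.chroms[f"chr{i+1}"] = seq
    return genome


def _draw_quality(rng: np.random.Generator, subthreshold: bool) -> tuple[float, int, float, int]:
    if subthreshold:
        qual = float(rng.uniform(0, 20))
        dp = int(rng.integers(0, 5))
        mq = float(rng.uniform(0, 30))
    else:
        qual = float(rng.uniform(40, 900))
        dp = int(rng.integers(10, 60))
        mq = float(rng.uniform(35, 60))
    dv = int(max(1, dp // 2))
    return qual, dp, mq, dv


def _blocked(occupied: set[int], start: int, end: int) -> bool:
    return any(p in occupied for p in range(start, end + 1))


def _draw_variant(
    rng: np.random.Generator,
    genome: Genome,
    chrom: str,
    occupied: set[int],
    keep_out: set[int],
    indel_fraction: float,
    subthreshold: bool,
    line_id: str,
    max_tries: int = 200,
) -> Variant:
    """One collision-free, left-normalized background variant."""
    seq = genome.chroms[chrom]
    n = len(seq)
    for _ in range(max_tries):
        pos = int(rng.integers(2, n - 4))  # 1-based; margin for short indels
        is_indel = rng.random() < indel_fraction
        if is_indel:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                ref = seq[pos - 1 : pos + length]
                alt = ref[0]
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + "".join(
                    rng.choice(_BASES, size=length).tobytes().decode("ascii")
                )
        else:
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        qual, dp, mq, dv = _draw_quality(rng, subthreshold)
        v = Variant(chrom, pos, ref, alt, qual=qual, dp=dp, mq=mq, dv=dv,
                    line_id=line_id)
        v = normalize_variant(v, genome)
        if v is None:
            continue
        s, e = v.span
        if s < 2 or e > n - 1:
            continue
        if _blocked(occupied, s - 1, e + 1) or _blocked(keep_out, s, e):
            continue
        occupied.update(range(s - 1, e + 2))
        return v
    raise SimulationCapacityError(
        f"could not place a collision-free variant on {chrom} "
        f"after {max_tries} tries"
    )


def _intervals_to_set(intervals: Optional[Sequence[tuple[str, int, int]]],
                      chrom: str) -> set[int]:
    out: set[int] = set()
    for c, s, e in intervals or ():
        if c == chrom:
            out.update(range(s, e + 1))
    return out


def simulate_cohort(
    genome: Genome,
    config: SimulationConfig,
    keep_out: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[dict[str, VariantSet], VariantSet]:
    """Shared cultivar variants plus per-line private background.

    Returns (line_id -> VariantSet, shared set S).  Every line's set is a
    superset of S; private variants never overlap S or each other within a
    line.  ``keep_out`` lists 1-based inclusive intervals (chrom, start,
    end) that receive no background variants at all — used to keep audit
    windows clean in planted fixtures.
    """
    if not genome.chroms:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(config.seed)
    shared = VariantSet(line_id="shared")
    shared_occupied: dict[str, set[int]] = {}
    for chrom, seq in genome.chroms.items():
        ko = _intervals_to_set(keep_out, chrom)
        occ: set[int] = set()
        n_shared = rng.poisson(len(seq) * config.shared_variant_rate)
        for _ in range(n_shared):
            sub = rng.random() < config.subthreshold_fraction
            shared.add(
                _draw_variant(rng, genome, chrom, occ, ko,
                              config.shared_indel_fraction, sub, "shared")
            )
        shared_occupied[chrom] = occ

    cohort: dict[str, VariantSet] = {}
    for line_id in config.wt_line_ids + config.edited_line_ids:
        vs = VariantSet(
            (replace(v, line_id=line_id) for v in shared), line_id=line_id
        )
        for chrom, seq in genome.chroms.items():
            ko = _intervals_to_set(keep_out, chrom)
            occ = set(shared_occupied[chrom])
            n_private = rng.poisson(len(seq) * config.private_variant_rate)
            for _ in range(n_private):
                sub = rng.random() < config.subthreshold_fraction
                vs.add(
                    _draw_variant(rng, genome, chrom, occ, ko,
                                  config.shared_indel_fraction, sub, line_id)
                )
        cohort[line_id] = vs
    return cohort, shared


# ---------------------------------------------------------------------------
# Planted edits

@dataclass(frozen=True)
class EditRequest:
    """A requested planted edit at a known candidate site."""

    line_id: str
    kind: str  # on_target | off_target
    sgrna_id: str
    site: OffTargetSite
    zone: str = "core"  # core | flank
    edit: str = "insertion"  # insertion | deletion
    length: int = 1


@dataclass(frozen=True)
class PlantedEdit:
    """Truth-table entry for one planted edit."""

    line_id: str
    kind: str
    sgrna_id: str
    site: OffTargetSite
    variant: Variant
    zone: str


def plant_edits(
    genome: Genome,
    guides: Sequence[GuideRNA],
    sites: Sequence[OffTargetSite],
    requests: Sequence[EditRequest],
    seed: int = 0,
    flank: int = 100,
) -> tuple[dict[str, list[Variant]], list[PlantedEdit]]:
    """Create the requested edits as variants anchored in their zones.

    Core edits anchor inside the protospacer+PAM footprint; flank edits
    anchor within +/-``flank`` bp of it but outside the core.  Planted
    edits within one fixture never overlap each other.
    """
    site_keys = {(s.sgrna_id, s.chrom, s.start, s.strand) for s in sites}
    rng = np.random.default_rng(seed)
    additions: dict[str, list[Variant]] = {}
    truth: list[PlantedEdit] = []
    occupied: dict[str, set[int]] = {}
    for req in requests:
        if (req.site.sgrna_id, req.site.chrom, req.site.start,
                req.site.strand) not in site_keys:
            raise ValueError("requested site is not in the provided site list")
        if req.length < 1:
            raise ValueError("edit length must be >= 1")
        seq = genome.chroms[req.site.chrom]
        fs, fe = req.site.footprint  # 0-based half-open
        if req.zone == "core":
            candidates = list(range(fs + 1, fe + 1))  # 1-based anchors
        else:
            candidates = list(range(max(2, fs + 1 - flank), fs + 1)) + list(
                range(fe + 1, min(len(seq) - 1, fe + flank) + 1)
            )
        rng.shuffle(candidates)
        occ = occupied.setdefault(req.site.chrom, set())
        placed = None
        for pos in candidates:
            if req.edit == "deletion":
                if pos + req.length > len(seq) - 1:
                    continue
                ref = seq[pos - 1 : pos + req.length]
                alt = ref[0]
            else:
                ref = seq[pos - 1]
                alt = ref + "".join(
                    rng.choice(_BASES, size=req.length).tobytes().decode("ascii")
                )
            qual, dp, mq, dv = _draw_quality(rng, subthreshold=False)
            v = Variant(req.site.chrom, pos, ref, alt, qual=qual, dp=dp,
                        mq=mq, dv=dv, line_id=req.line_id)
            v = normalize_variant(v, genome)
            if v is None:
                continue
            s, e = v.span
            # left-normalization can shift an edit out of its zone when the
            # edited bases repeat the upstream sequence; re-draw if so
            anchor = (v.pos, v.pos) if len(v.alt) > len(v.ref) else (s, e)
            in_core = anchor[0] <= fe and anchor[1] >= fs + 1
            if (req.zone == "core") != in_core:
                continue
            if _blocked(occ, s - 1, e + 1):
                continue
            occ.update(range(s - 1, e + 2))
            placed = v
            break
        if placed is None:
            raise SimulationCapacityError(
                f"zone too crowded to place a {req.edit} of length "
                f"{req.length} at {req.site.chrom}:{req.site.start}"
            )
        additions.setdefault(req.line_id, []).append(placed)
        truth.append(
            PlantedEdit(req.line_id, req.kind, req.sgrna_id, req.site,
                        placed, req.zone)
        )
    return additions, truth


# ---------------------------------------------------------------------------
# Synthetic annotation

def make_annotation_gff(genome: Genome, gene_spacing: int = 10_000) -> str:
    """One multi-exon gene model per ``gene_spacing`` bp of each chromosome.

    Each gene carries 5'/3' UTRs, two CDS exons and an intron, so every
    region category (exonic, UTR, intronic, up/downstream, intergenic) is
    reachable at the default 1 kb flank window.
    """
    lines = ["##gff-version 3"]
    gi = 0
    for chrom, seq in genome.chroms.items():
        lines.append(f"##sequence-region {chrom} 1 {len(seq)}")
        for block in range(0, len(seq) - 8000, gene_spacing):
            gi += 1
            strand = "+" if gi % 2 else "-"
            g0 = block + 2001  # gene start, 1-based
            g1 = block + 7000
            gid = f"gene{gi}"

            def feat(ftype, start, end, attrs):
                lines.append(
                    f"{chrom}\tcasaudit\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
                )

            feat("gene", g0, g1, f"ID={gid}")
            feat("mRNA", g0, g1, f"ID={gid}.1;Parent={gid}")
            feat("exon", g0, block + 3000, f"ID={gid}.1.e1;Parent={gid}.1")
            feat("exon", block + 4001, g1, f"ID={gid}.1.e2;Parent={gid}.1")
            if strand == "+":
                feat("five_prime_UTR", g0, block + 2200,
                     f"ID={gid}.1.u5;Parent={gid}.1")
                feat("CDS", block + 2201, block + 3000,
                     f"ID={gid}.1.c1;Parent={gid}.1")
                feat("CDS", block + 4001, block + 6800,
                     f"ID={gid}.1.c2;Parent={gid}.1")
                feat("three_prime_UTR", block + 6801, g1,
                     f"ID={gid}.1.u3;Parent={gid}.1")
            else:
                feat("three_prime_UTR", g0, block + 2200,
                     f"ID={gid}.1.u3;Parent={gid}.1")
                feat("CDS", block + 2201, block + 3000,
                     f"ID={gid}.1.c1;Parent={gid}.1")
                feat("CDS", block + 4001, block + 6800,
                     f"ID={gid}.1.c2;Parent={gid}.1")
                feat("five_prime_UTR", block + 6801, g1,
                     f"ID={gid}.1.u5;Parent={gid}.1")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Fixture I/O

TRUTH_COLUMNS = [
    "line_id", "kind", "sgrna_id", "chrom", "site_start", "strand", "zone",
    "pos", "ref", "alt",
]


def write_fixture(
    outdir,
    genome: Genome,
    cohort: dict[str, VariantSet],
    guides: Sequence[GuideRNA],
    truth: Sequence[PlantedEdit] = (),
) -> Path:
    """Write genome FASTA, per-line VCFs, guides TSV, GFF3 and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.to_fasta(outdir / "genome.fa")
    for line_id, vs in cohort.items():
        write_variants(vs, outdir / f"{line_id}.vcf", genome=genome)
    with open(outdir / "guides.tsv", "w") as fh:
        fh.write("id\tspacer\n")
        for g in guides:
            fh.write(f"{g.id}\t{g.spacer}\n")
    (outdir / "genes.gff3").write_text(make_annotation_gff(genome))
    rows = [
        {
            "line_id": t.line_id, "kind": t.kind, "sgrna_id": t.sgrna_id,
            "chrom": t.site.chrom, "site_start": t.site.start,
            "strand": t.site.strand, "zone": t.zone, "pos": t.variant.pos,
            "ref": t.variant.ref, "alt": t.variant.alt,
        }
        for t in truth
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    return outdir


def read_guides_tsv(path) -> list[GuideRNA]:
    df = pd.read_csv(path, sep="\t")
    return [GuideRNA(str(r.id), str(r.spacer)) for r in df.itertuples()]


@dataclass
class Fixture:
    genome: Genome
    cohort: dict[str, VariantSet]
    guides: list[GuideRNA]
    truth: pd.DataFrame
    outdir: Optional[Path] = None


def read_fixture(fixture_dir) -> Fixture:
    """Re-read a written fixture; round-trips the in-memory objects."""
    fixture_dir = Path(fixture_dir)
    genome = Genome.from_fasta(fixture_dir / "genome.fa")
    cohort = {}
    for vcf in sorted(fixture_dir.glob("*.vcf")):
        line_id = vcf.stem
        cohort[line_id] = load_variants(vcf, line_id=line_id, genome=genome)
    guides = read_guides_tsv(fixture_dir / "guides.tsv")
    truth = pd.read_csv(fixture_dir / "truth.tsv", sep="\t")
    return Fixture(genome, cohort, guides, truth, outdir=fixture_dir)


# ---------------------------------------------------------------------------
# Planted audit fixture

@dataclass
class PlantedFixture:
    """A full audit scenario with known answers."""

    genome: Genome
    guides: list[GuideRNA]
    cohort: dict[str, VariantSet]
    shared: VariantSet
    sites: list[OffTargetSite]
    truth: list[PlantedEdit]
    config: SimulationConfig


def _embed(seq: str, pos0: int, insert: str) -> str:
    return seq[:pos0] + insert + seq[pos0 + len(insert):]


def make_planted_fixture(
    seed: int,
    genome_length: int = 50_000,
    n_wt_lines: int = 3,
    n_edited_lines: int = 2,
    offtarget_mismatches: int = 3,
    offtarget_edit_length: int = 35,
    search_params: SearchParams = SearchParams(),
    flank: int = 100,
) -> PlantedFixture:
    """A 50-kb audit scenario with two guides and three planted edits.

    Both guides get an exact on-target site; guide 1 additionally gets an
    embedded near-match (``offtarget_mismatches`` substitutions) with an
    NGG PAM.  Planted edits: a +1 on-target insertion in ED_1, a -3
    on-target deletion in ED_2, and an off-target core insertion (default
    35 bp, the shape of a real validated off-target event) in ED_2.
    Background variants are excluded from every candidate-site flank
    window, so the truth table is the complete answer key.
    """
    rng = np.random.default_rng(seed)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    genome = generate_genome(genome_length, 1, gc=0.35, seed=sub_seed)
    chrom = "chr1"
    seq = genome.chroms[chrom]

    def rand_spacer() -> str:
        return rng.choice(_BASES, size=20).tobytes().decode("ascii")

    spacer1, spacer2 = rand_spacer(), rand_spacer()
    jitter_span = max(1, genome_length // 50)
    jitter = lambda: int(rng.integers(0, jitter_span))
    o1 = genome_length // 10 + jitter()
    o2 = (2 * genome_length) // 5 + jitter()
    o3 = (7 * genome_length) // 10 + jitter()
    # exact on-target protospacers with a TGG PAM
    seq = _embed(seq, o1, spacer1 + "TGG")
    seq = _embed(seq, o2, spacer2 + "TGG")
    # near-match off-target for guide 1
    off = list(spacer1)
    for i in rng.choice(20, size=offtarget_mismatches, replace=False):
        off[i] = str(rng.choice([b for b in "ACGT" if b != off[i]]))
    seq = _embed(seq, o3, "".join(off) + "TGG")
    genome.chroms[chrom] = seq

    guides = [GuideRNA("sgRNA1", spacer1), GuideRNA("sgRNA2", spacer2)]
    sites: list[OffTargetSite] = []
    for g in guides:
        sites.extend(find_offtarget_sites(genome, g, search_params))

    keep_out = [
        (s.chrom, s.footprint[0] + 1 - flank - 10, s.footprint[1] + flank + 10)
        for s in sites
    ]
    config = SimulationConfig(
        genome_length=genome_length,
        n_wt_lines=n_wt_lines,
        n_edited_lines=n_edited_lines,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cohort, shared = simulate_cohort(genome, config, keep_out=keep_out)

    def locate(sgrna_id: str, start: int) -> OffTargetSite:
        for s in sites:
            if s.sgrna_id == sgrna_id and s.start == start and s.strand == "+":
                return s
        raise RuntimeError(f"embedded site {sgrna_id}@{start} not recovered")

    on1 = locate("sgRNA1", o1)
    on2 = locate("sgRNA2", o2)
    off1 = locate("sgRNA1", o3)
    edited = config.edited_line_ids
    requests = [
        EditRequest(edited[0], "on_target", "sgRNA1", on1, "core",
                    "insertion", 1),
        EditRequest(edited[-1], "on_target", "sgRNA2", on2, "core",
                    "deletion", 3),
        EditRequest(edited[-1], "off_target", "sgRNA1", off1, "core",
                    "insertion", offtarget_edit_length),
    ]
    additions, truth = plant_edits(
        genome, guides, sites, requests,
        seed=int(rng.integers(0, 2**31 - 1)), flank=flank,
    )
    for line_id, variants in additions.items():
        for v in variants:
            cohort[line_id].add(v)
    return PlantedFixture(genome, guides, cohort, shared, sites, truth, config)
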