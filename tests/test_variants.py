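"""Variant ingestion, normalization, filtering, set algebra and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casaudit import (
    FilterThresholds,
    GeneAnnotation,
    Genome,
    Variant,
    VariantSet,
    annotate_regions,
    classify_variant,
    core_variants,
    diff_vs_core,
    filter_variants,
    generate_genome,
    indel_length_distribution,
    load_variants,
    normalize_variant,
    private_variants,
    substitution_spectrum,
    write_variants,
)
from casaudit.simulate import SimulationConfig, make_annotation_gff, simulate_cohort
from casaudit.variants import SPECTRUM_KEYS

from helpers import oracle_normalize


def _vs(*keys, line_id=""):
    return VariantSet(
        (Variant("chr1", pos, ref, alt) for (pos, ref, alt) in keys),
        line_id=line_id,
    )


# ---------------------------------------------------------------------------
# VCF I/O

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="mapq">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tT\t50\t.\tDP=12;MQ=40
chr1\t200\t.\tG\tT,C\t60\t.\tDP=20;MQ=50
chr1\t300\t.\tC\t<DEL>\t60\t.\tDP=20;MQ=50
"""


def test_load_variants_maps_fields_and_splits_multiallelic(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(VCF_TEXT)
    vs = load_variants(path, line_id="L1")
    assert len(vs) == 3  # one SNP + biallelic split; symbolic allele skipped
    v = vs.get(("chr1", 100, "A", "T"))
    assert (v.qual, v.dp, v.mq, v.line_id) == (50.0, 12, 40.0, "L1")
    alts = {v.alt for v in vs if v.pos == 200}
    assert alts == {"T", "C"}


def test_write_then_load_roundtrip(tmp_path, small_genome):
    # use real genome bases so normalization on reload is a no-op
    vs = VariantSet(line_id="L1")
    for p in (10, 50, 90):
        ref = small_genome.base("chr1", p)
        alt = "ACGT".replace(ref, "")[0]
        vs.add(Variant("chr1", p, ref, alt, qual=99, dp=30, mq=50, dv=12,
                       line_id="L1"))
    path = tmp_path / "rt.vcf"
    write_variants(vs, path, genome=small_genome)
    back = load_variants(path, line_id="L1", genome=small_genome)
    assert back == vs
    v = back.get(next(iter(vs)).key)
    assert v.dv == 12 and v.dp == 30


def test_load_missing_file_raises(tmp_path):
    with pytest.raises(IOError):
        load_variants(tmp_path / "nope.vcf", line_id="x")


# ---------------------------------------------------------------------------
# Normalization

def test_normalize_null_variant_rejected():
    g = Genome(chroms={"chr1": "GGGGGGGGGATAAATGGGG"})
    assert normalize_variant(Variant("chr1", 10, "AT", "AT"), g) is None


def test_normalize_left_aligns_deletion_in_repeat():
    #                 123456789012345
    g = Genome(chroms={"chr1": "GGGGGGGGCAAATGG"})
    v = normalize_variant(Variant("chr1", 9, "CAA", "CA"), g)
    assert (v.pos, v.ref, v.alt) == (9, "CA", "C")
    exp = oracle_normalize(g.chroms["chr1"], 9, "CAA", "CA")
    assert (v.pos, v.ref, v.alt) == exp


def test_normalize_ref_mismatch_raises(small_genome):
    ref = small_genome.base("chr1", 100)
    wrong = "ACGT".replace(ref, "")[0]
    with pytest.raises(ValueError, match="ref mismatch"):
        normalize_variant(Variant("chr1", 100, wrong, ref), small_genome)


@pytest.mark.parametrize("seed", range(6))
def test_normalize_matches_bruteforce_oracle_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    genome = generate_genome(600, 1, gc=0.3, seed=seed + 100)
    seq = genome.chroms["chr1"]
    for _ in range(60):
        pos = int(rng.integers(80, 500))
        kind = rng.integers(0, 3)
        if kind == 0:  # SNP
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif kind == 1:  # deletion, possibly unnormalized
            d = int(rng.integers(1, 4))
            ref = seq[pos - 1 : pos + d]
            alt = ref[0]
        else:  # insertion
            ref = seq[pos - 1]
            alt = ref + "".join(rng.choice(list("ACGT"), size=rng.integers(1, 4)))
        v = normalize_variant(Variant("chr1", pos, ref, alt), genome)
        exp = oracle_normalize(seq, pos, ref, alt)
        if v is None:
            assert exp is None
            continue
        assert (v.pos, v.ref, v.alt) == exp
        again = normalize_variant(v, genome)
        assert (again.pos, again.ref, again.alt) == (v.pos, v.ref, v.alt)


# ---------------------------------------------------------------------------
# Filter

def test_filter_strict_inequalities():
    t = FilterThresholds()
    keep = Variant("chr1", 1, "A", "T", qual=35, dp=10, mq=40)
    boundary = Variant("chr1", 2, "A", "T", qual=20, dp=10, mq=40)
    vs = VariantSet([keep, boundary])
    out = filter_variants(vs, t)
    assert keep in out and boundary not in out
    assert len(filter_variants(VariantSet())) == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    quals=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20),
    bump=st.floats(0, 30),
)
def test_filter_monotone_in_thresholds(quals, bump):
    vs = VariantSet(
        Variant("chr1", i + 1, "A", "T", qual=q, dp=10, mq=50)
        for i, q in enumerate(quals)
    )
    low = filter_variants(vs, FilterThresholds(min_qual=10))
    high = filter_variants(vs, FilterThresholds(min_qual=10 + bump))
    assert high.keys() <= low.keys()


# ---------------------------------------------------------------------------
# Set algebra

def test_core_is_exact_intersection():
    wt1 = _vs((1, "A", "T"), (2, "C", "G"), (3, "G", "A"))
    wt2 = _vs((2, "C", "G"), (3, "G", "A"), (4, "T", "C"))
    wt3 = _vs((3, "G", "A"), (5, "A", "C"))
    assert core_variants([wt1, wt2, wt3]).keys() == {("chr1", 3, "G", "A")}
    assert core_variants([wt1, wt1, wt1]) == wt1
    assert len(core_variants([_vs((1, "A", "T")), _vs((2, "C", "G"))])) == 0
    with pytest.raises(ValueError):
        core_variants([wt1])


def test_private_uses_union_of_wildtypes():
    wt1, wt2, wt3 = _vs((1, "A", "T")), _vs((2, "C", "G")), _vs((3, "G", "A"))
    edited = _vs((1, "A", "T"), (2, "C", "G"), (3, "G", "A"),
                 (7, "T", "A"), (8, "G", "C"))
    priv = private_variants(edited, [wt1, wt2, wt3])
    assert priv.keys() == {("chr1", 7, "T", "A"), ("chr1", 8, "G", "C")}
    # a variant in only one WT line is still excluded
    assert ("chr1", 1, "A", "T") not in priv
    with pytest.raises(ValueError):
        private_variants(edited, [])


def test_diff_vs_core_and_ordering_invariant():
    core = _vs((1, "A", "T"))
    edited = _vs((1, "A", "T"), (2, "C", "G"))
    assert diff_vs_core(edited, core).keys() == {("chr1", 2, "C", "G")}
    assert len(diff_vs_core(core, core)) == 0


def test_set_algebra_invariants_on_random_cohort():
    genome = generate_genome(8000, 1, gc=0.4, seed=9)
    config = SimulationConfig(genome_length=8000, n_edited_lines=2,
                              private_variant_rate=0.002, seed=9)
    cohort, shared = simulate_cohort(genome, config)
    wt = [cohort[l] for l in config.wt_line_ids]
    core = core_variants(wt)
    for w in wt:
        assert core.keys() <= w.keys()
    for lid in config.edited_line_ids:
        edited = cohort[lid]
        priv = private_variants(edited, wt)
        dvc = diff_vs_core(edited, core)
        assert priv.keys() <= dvc.keys() <= edited.keys()
        assert len(priv) <= len(dvc)


# ---------------------------------------------------------------------------
# Typing and summaries

@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "T", ("SNP", 0)),
        ("G", "G" + "ACGTA" * 7, ("insertion", 35)),
        ("C" + "A" * 29, "C", ("deletion", 29)),
        ("AT", "GC", ("complex", 0)),
    ],
)
def test_classify_variant(ref, alt, expected):
    assert classify_variant(Variant("chr1", 10, ref, alt)) == expected


def test_substitution_spectrum_sums_and_null_case():
    vs = VariantSet(Variant("chr1", i + 1, "A", "G") for i in range(4))
    spec = substitution_spectrum(vs)
    assert spec["A>G"] == 100.0
    assert sum(spec.values()) == pytest.approx(100.0, abs=1e-9)
    assert set(spec) == set(SPECTRUM_KEYS)
    empty = substitution_spectrum(VariantSet())
    assert all(v == 0.0 for v in empty.values())


def test_substitution_spectrum_transition_fraction():
    # 200 transitions (A>G) and 100 transversions (A>C): 2:1 exactly
    vs = VariantSet(
        [Variant("chr1", i + 1, "A", "G") for i in range(200)]
        + [Variant("chr1", i + 1001, "A", "C") for i in range(100)]
    )
    spec = substitution_spectrum(vs)
    transitions = spec["A>G"] + spec["G>A"] + spec["C>T"] + spec["T>C"]
    assert transitions == pytest.approx(200 / 3 * 1, abs=1e-9)
    assert sum(spec.values()) == pytest.approx(100.0, abs=1e-9)


def test_indel_length_distribution():
    vs = VariantSet(
        [
            Variant("chr1", 1, "A", "AT"),      # +1
            Variant("chr1", 10, "AT", "A"),     # -1
            Variant("chr1", 20, "ATG", "A"),    # -2
            Variant("chr1", 30, "GCA", "G"),    # -2
            Variant("chr1", 40, "C", "T"),      # SNP, excluded
        ]
    )
    assert indel_length_distribution(vs) == {-2: 2, -1: 1, 1: 1}
    assert indel_length_distribution(VariantSet()) == {}


# ---------------------------------------------------------------------------
# Region annotation

def test_annotate_regions_categories_and_partition(tmp_path):
    genome = generate_genome(12000, 1, gc=0.4, seed=3)
    gff = tmp_path / "genes.gff3"
    gff.write_text(make_annotation_gff(genome))
    ann = GeneAnnotation(gff)
    # gene1 occupies 2001-7000: CDS 2201-3000 & 4001-6800, UTRs at the ends,
    # intron 3001-4000
    cases = {
        2500: "exonic",
        2100: "UTR",
        3500: "intronic",
        1500: "upstream",   # 500 bp 5' of the + strand gene
        7500: "downstream",
        9500: "intergenic",
    }
    vs = VariantSet(Variant("chr1", p, "A", "T") for p in cases)
    assigned, counts = annotate_regions(vs, ann, flank_window=1000)
    for pos, cat in cases.items():
        assert assigned[("chr1", pos, "A", "T")] == cat, pos
    assert sum(counts.values()) == len(vs)


def test_annotation_without_genes_raises(tmp_path):
    gff = tmp_path / "empty.gff3"
    gff.write_text("##gff-version 3\n")
    with pytest.raises(ValueError, match="no gene"):
        GeneAnnotation(gff)
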