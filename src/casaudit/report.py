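"""End-to-end off-target audit: site/variant intersection and summary tables.

The audit asks, for every candidate target site of every guide, whether an
edited line carries a private variant inside the site (core zone, the
protospacer plus PAM) or within a +/-100 bp flank.  Private variants are by
construction absent from all wild-type lines, so a core-zone hit is a
candidate bona fide off-target mutation.  On-target mutations (at the
0-mismatch site of each guide) are typed separately as +k insertions and
-k deletions, the signature of NHEJ repair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .correction import NewSiteReport, apply_variants, find_new_sites
from .genome import Genome
from .search import GuideRNA, OffTargetSite, SearchParams, find_offtarget_sites
from .variants import (
    FilterThresholds,
    GeneAnnotation,
    REGION_CATEGORIES,
    Variant,
    VariantSet,
    annotate_regions,
    classify_variant,
    core_variants,
    diff_vs_core,
    filter_variants,
    load_variants,
    private_variants,
)


@dataclass(frozen=True)
class AuditParams:
    """Window geometry of the audit.

    ``flank`` is the distance screened either side of a site footprint;
    the core zone is the protospacer (plus PAM unless disabled).  On-target
    typing allows ``cut_site_slack`` bp around the footprint because Cas9
    cuts 3 bp 5' of the PAM and NHEJ scars spread from the cut.
    ``exclude_on_target`` keeps 0-mismatch sites out of the off-target
    numerators (they are reported in the on-target table instead).
    """

    flank: int = 100
    include_pam_in_core: bool = True
    cut_site_slack: int = 3
    exclude_on_target: bool = True

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class AuditHit:
    """One (site, private variant) intersection."""

    site: OffTargetSite
    variant: Variant
    line_id: str
    zone: str  # core | flank
    variant_class: tuple  # (kind, length) from classify_variant


def _variant_interval(v: Variant) -> tuple[int, int]:
    """Interval used for window tests: insertions count by their anchor."""
    kind, _ = classify_variant(v)
    if kind == "insertion":
        return (v.pos, v.pos)
    return v.span


def _core_interval(site: OffTargetSite, include_pam: bool) -> tuple[int, int]:
    fs, fe = site.footprint  # 0-based half-open
    if include_pam:
        return (fs + 1, fe)
    L = len(site.protospacer)
    if site.strand == "+":
        return (fs + 1, fs + L)
    return (fs + 4, fe)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def site_variant_hits(
    sites: Sequence[OffTargetSite],
    private: VariantSet,
    params: AuditParams = AuditParams(),
) -> list[AuditHit]:
    """Intersect private variants with candidate-site windows.

    A hit is recorded when the variant's reference span (anchor base for
    insertions) intersects the footprint extended by ``flank`` on both
    sides; boundaries are inclusive.  Zone is core when the variant touches
    the protospacer (plus PAM by default), flank otherwise; each
    (site, variant) pair is reported once with the most specific zone.
    """
    hits: list[AuditHit] = []
    for site in sites:
        fs, fe = site.footprint
        window = (fs + 1 - params.flank, fe + params.flank)
        core = _core_interval(site, params.include_pam_in_core)
        for v in private:
            if v.chrom != site.chrom:
                continue
            iv = _variant_interval(v)
            if not _overlap(iv, window):
                continue
            zone = "core" if _overlap(iv, core) else "flank"
            hits.append(
                AuditHit(
                    site=site,
                    variant=v,
                    line_id=v.line_id or private.line_id,
                    zone=zone,
                    variant_class=classify_variant(v),
                )
            )
    return hits


def _mutation_label(v: Variant) -> str:
    kind, length = classify_variant(v)
    if kind == "insertion":
        return f"+{length}"
    if kind == "deletion":
        return f"-{length}"
    return kind


def classify_on_target_mutations(
    private_by_line: dict[str, VariantSet],
    on_target_sites: Sequence[OffTargetSite],
    params: AuditParams = AuditParams(),
) -> pd.DataFrame:
    """Per-line, per-guide table of mutation types at on-target sites.

    Every private variant intersecting an on-target footprint (+/- cut-site
    slack) is typed as +k / -k / SNP, with DV/DP carried through.  A
    deletion spanning the sites of two different guides is reported once
    per guide pair (label "gA+gB"), the signature of a fragment dropped
    between two cuts.
    """
    for s in on_target_sites:
        if s.n_mismatches != 0:
            raise ValueError("on-target sites must have 0 mismatches")
    rows = []
    for line_id in sorted(private_by_line):
        for v in private_by_line[line_id]:
            iv = _variant_interval(v)
            guides_hit: dict[str, OffTargetSite] = {}
            for s in on_target_sites:
                if s.chrom != v.chrom:
                    continue
                fs, fe = s.footprint
                zone = (fs + 1 - params.cut_site_slack, fe + params.cut_site_slack)
                if _overlap(iv, zone):
                    guides_hit.setdefault(s.sgrna_id, s)
            if not guides_hit:
                continue
            gids = sorted(guides_hit)
            kind, _ = classify_variant(v)
            if len(gids) >= 2 and kind == "deletion":
                # one inter-site record per adjacent guide pair
                labels = [f"{a}+{b}" for a, b in zip(gids, gids[1:])]
            else:
                labels = gids
            for label in labels:
                rows.append(
                    {
                        "line": line_id,
                        "sgrna": label,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "mutation": _mutation_label(v),
                        "dv": v.dv,
                        "dp": v.dp,
                    }
                )
    return pd.DataFrame(
        rows, columns=["line", "sgrna", "chrom", "pos", "mutation", "dv", "dp"]
    )


@dataclass
class AuditResult:
    """Bundle of every table the audit produces."""

    line_counts: pd.DataFrame
    offtarget_matrix: pd.DataFrame
    new_site_matrix: pd.DataFrame
    on_target_table: pd.DataFrame
    hits: list[AuditHit]
    new_site_hits: list[AuditHit]
    region_annotation: Optional[pd.DataFrame] = None
    sites: list[OffTargetSite] = field(default_factory=list)
    new_report: Optional[NewSiteReport] = None
    core: Optional[VariantSet] = None
    private_by_line: dict[str, VariantSet] = field(default_factory=dict)
    corrected_genome: Optional[Genome] = None


def _count_types(vs: VariantSet) -> tuple[int, int]:
    """(n_indel, n_snp); complex records count with the indels."""
    n_snp = sum(1 for v in vs if classify_variant(v)[0] == "SNP")
    return (len(vs) - n_snp, n_snp)


def _matrix_cell(m: int, n: int) -> str:
    return f"{m}/{n}"


def run_audit(
    genome: Genome | str | Path,
    wt_vcfs: Sequence,
    edited_vcfs: Sequence,
    guides: Sequence[GuideRNA],
    gff: Optional[object] = None,
    search_params: SearchParams = SearchParams(),
    audit_params: AuditParams = AuditParams(),
    thresholds: FilterThresholds = FilterThresholds(),
    flank_window: int = 1000,
    line_ids: Optional[dict] = None,
) -> AuditResult:
    """Execute the whole audit on a reference, per-line VCFs and guides.

    Stages: load -> normalize -> filter -> core/private set algebra ->
    site search on the original genome -> site/variant hits -> on-target
    typing -> cultivar correction by the core set -> new-site discovery ->
    hits at new sites -> summary tables.  Deterministic given its inputs.
    """
    if not isinstance(genome, Genome):
        genome = Genome.from_fasta(genome)
    if len(wt_vcfs) < 2 or len(edited_vcfs) < 1:
        raise ValueError("need >=2 wild-type and >=1 edited line")

    def _load(item, default_id):
        if isinstance(item, VariantSet):
            return item
        vs = load_variants(item, line_id=default_id, genome=genome)
        return vs

    wt_sets = [
        filter_variants(_load(p, f"WT_{i+1}"), thresholds)
        for i, p in enumerate(wt_vcfs)
    ]
    if line_ids:
        for s in wt_sets:
            s.line_id = line_ids.get(s.line_id, s.line_id)
    edited_sets = [
        filter_variants(_load(p, f"ED_{i+1}"), thresholds)
        for i, p in enumerate(edited_vcfs)
    ]

    core = core_variants(wt_sets)
    private_by_line = {
        es.line_id: private_variants(es, wt_sets) for es in edited_sets
    }
    for lid, vs in private_by_line.items():
        vs.line_id = lid

    # Table 1 shape: per-line counts vs reference, vs core, private
    rows = []
    for s in wt_sets:
        ind, snp = _count_types(s)
        rows.append(
            {"line": s.line_id, "role": "WT", "indel_vs_ref": ind, "snp_vs_ref": snp,
             "indel_vs_wt": None, "snp_vs_wt": None,
             "indel_private": None, "snp_private": None}
        )
    for es in edited_sets:
        ind, snp = _count_types(es)
        dvc = diff_vs_core(es, core)
        ind_c, snp_c = _count_types(dvc)
        ind_p, snp_p = _count_types(private_by_line[es.line_id])
        rows.append(
            {"line": es.line_id, "role": "edited", "indel_vs_ref": ind,
             "snp_vs_ref": snp, "indel_vs_wt": ind_c, "snp_vs_wt": snp_c,
             "indel_private": ind_p, "snp_private": snp_p}
        )
    line_counts = pd.DataFrame(rows)

    # Table 2 shape: region annotation per line
    region_annotation = None
    if gff is not None:
        ann = gff if isinstance(gff, GeneAnnotation) else GeneAnnotation(gff)
        ann_rows = []
        for s in wt_sets + edited_sets:
            _, counts = annotate_regions(s, ann, flank_window)
            ann_rows.append({"line": s.line_id, **counts})
        region_annotation = pd.DataFrame(
            ann_rows, columns=["line", *REGION_CATEGORIES]
        )

    # Site search on the original genome
    sites: list[OffTargetSite] = []
    for g in guides:
        sites.extend(find_offtarget_sites(genome, g, search_params))

    hits: list[AuditHit] = []
    for lid, vs in private_by_line.items():
        hits.extend(site_variant_hits(sites, vs, audit_params))

    # Table 3 shape: per (line, guide) "mutations/sites" by PAM class.
    pam_order = [c for c in ("NGG", "NAG", "NGA") if c in search_params.pam_classes]
    denom = {
        (g.id, c): sum(
            1 for s in sites if s.sgrna_id == g.id and s.pam_class == c
        )
        for g in guides
        for c in pam_order
    }
    mat_rows = []
    for lid in sorted(private_by_line):
        for g in guides:
            cells = {}
            for c in pam_order:
                numer = len(
                    {
                        h.variant.key
                        for h in hits
                        if h.line_id == lid
                        and h.site.sgrna_id == g.id
                        and h.site.pam_class == c
                        and h.zone == "core"
                        and not (
                            audit_params.exclude_on_target
                            and h.site.n_mismatches == 0
                        )
                    }
                )
                cells[c] = _matrix_cell(numer, denom[(g.id, c)])
            mat_rows.append({"line": lid, "sgrna": g.id, **cells})
    offtarget_matrix = pd.DataFrame(mat_rows, columns=["line", "sgrna", *pam_order])

    # On-target typing at 0-mismatch sites
    on_sites = [s for s in sites if s.n_mismatches == 0]
    on_target_table = classify_on_target_mutations(
        private_by_line, on_sites, audit_params
    )

    # Cultivar correction and new-site audit
    corrected, lmap, _skipped = apply_variants(genome, core)
    new_report = find_new_sites(
        sites, corrected, genome, list(guides), search_params, lmap
    )
    new_site_hits: list[AuditHit] = []
    for lid, vs in private_by_line.items():
        lifted = VariantSet(line_id=lid)
        for v in vs:
            p = lmap.lift(v.chrom, v.pos)
            if p is not None:
                lifted.add(replace(v, pos=p))
        new_site_hits.extend(
            site_variant_hits([ns.site for ns in new_report.new_sites], lifted,
                              audit_params)
        )

    # Table 4 shape: per-guide new-site counts as "mutations/sites"
    new_counts = new_report.per_guide_class_counts([g.id for g in guides], pam_order)
    t4_rows = []
    for g in guides:
        cells = {}
        for c in pam_order:
            numer = len(
                {
                    h.variant.key
                    for h in new_site_hits
                    if h.site.sgrna_id == g.id
                    and h.site.pam_class == c
                    and h.zone == "core"
                }
            )
            cells[c] = _matrix_cell(numer, new_counts[g.id][c])
        t4_rows.append({"sgrna": g.id, **cells})
    new_site_matrix = pd.DataFrame(t4_rows, columns=["sgrna", *pam_order])

    return AuditResult(
        line_counts=line_counts,
        offtarget_matrix=offtarget_matrix,
        new_site_matrix=new_site_matrix,
        on_target_table=on_target_table,
        hits=hits,
        new_site_hits=new_site_hits,
        region_annotation=region_annotation,
        sites=sites,
        new_report=new_report,
        core=core,
        private_by_line=private_by_line,
        corrected_genome=corrected,
    )


def _hits_frame(hits: Sequence[AuditHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line": h.line_id,
                "sgrna": h.site.sgrna_id,
                "chrom": h.site.chrom,
                "site_start": h.site.start,
                "strand": h.site.strand,
                "pam_class": h.site.pam_class,
                "n_mismatches": h.site.n_mismatches,
                "zone": h.zone,
                "pos": h.variant.pos,
                "ref": h.variant.ref,
                "alt": h.variant.alt,
                "class": h.variant_class[0],
                "length": h.variant_class[1],
            }
            for h in hits
        ],
        columns=[
            "line", "sgrna", "chrom", "site_start", "strand", "pam_class",
            "n_mismatches", "zone", "pos", "ref", "alt", "class", "length",
        ],
    )


def write_report(result: AuditResult, outdir) -> None:
    """Write every audit table as TSV plus a JSON bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.line_counts.to_csv(outdir / "table1_counts.tsv", sep="\t", index=False)
    if result.region_annotation is not None:
        result.region_annotation.to_csv(
            outdir / "table2_annotation.tsv", sep="\t", index=False
        )
    result.offtarget_matrix.to_csv(
        outdir / "table3_offtarget_matrix.tsv", sep="\t", index=False
    )
    result.new_site_matrix.to_csv(
        outdir / "table4_new_sites.tsv", sep="\t", index=False
    )
    result.on_target_table.to_csv(
        outdir / "on_target_types.tsv", sep="\t", index=False
    )
    _hits_frame(result.hits).to_csv(outdir / "audit_hits.tsv", sep="\t", index=False)
    bundle = {
        "table1_counts": result.line_counts.to_dict(orient="records"),
        "table3_offtarget_matrix": result.offtarget_matrix.to_dict(orient="records"),
        "table4_new_sites": result.new_site_matrix.to_dict(orient="records"),
        "on_target_types": result.on_target_table.to_dict(orient="records"),
        "n_sites": len(result.sites),
        "n_new_sites": (
            len(result.new_report.new_sites) if result.new_report else 0
        ),
        "n_hits": len(result.hits),
    }
    if result.region_annotation is not None:
        bundle["table2_annotation"] = result.region_annotation.to_dict(
            orient="records"
        )
    with open(outdir / "audit_bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
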