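"""Cultivar correction of the reference genome and coordinate liftover.

Variants shared by every wild-type line are interpreted as differences
between the transformed cultivar and the reference assembly, not as edits.
Applying them yields a "corrected" genome in which candidate target sites
are re-enumerated; sites with no counterpart at the lifted locus in the
original reference are newly created by cultivar variation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .genome import Genome, reverse_complement
from .search import (
    GuideRNA,
    OffTargetSite,
    SearchParams,
    classify_pam,
    count_mismatches,
    find_offtarget_sites,
)
from .variants import Variant, VariantSet


@dataclass
class LiftoverMap:
    """Per-chromosome ordered blocks mapping original to corrected positions.

    Each block is (orig_start, orig_end, corrected_start), 1-based inclusive,
    mapping orig_start+i -> corrected_start+i.  Positions inside deleted
    reference spans are not covered by any block and lift to None.
    """

    blocks: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    orig_lengths: dict[str, int] = field(default_factory=dict)
    corr_lengths: dict[str, int] = field(default_factory=dict)

    def lift(self, chrom: str, pos: int):
        """Corrected 1-based position, or None when the base was deleted."""
        blocks = self.blocks.get(chrom)
        if blocks is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self.orig_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        i = bisect.bisect_right(blocks, (pos, float("inf"), 0)) - 1
        if i >= 0:
            start, end, corr = blocks[i]
            if start <= pos <= end:
                return corr + (pos - start)
        return None

    def lift_interval(self, chrom: str, start: int, end: int):
        """Lift a 1-based inclusive interval for overlap testing.

        Deleted endpoints shrink inward to the nearest surviving position;
        a fully deleted interval maps to the gap between its surviving
        flanks so that sites at indel boundaries are not dropped.
        Returns (corrected_start, corrected_end) or None when nothing maps.
        """
        blocks = self.blocks.get(chrom)
        if blocks is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        inside = [
            (c + max(s, start) - s, c + min(e, end) - s)
            for (s, e, c) in blocks
            if e >= start and s <= end
        ]
        if inside:
            return (min(lo for lo, _ in inside), max(hi for _, hi in inside))
        # fully deleted: bracket between surviving flanks
        left = [c + (e - s) for (s, e, c) in blocks if e < start]
        right = [c for (s, e, c) in blocks if s > end]
        if left and right:
            return (max(left), min(right))
        if left:
            return (max(left), max(left))
        if right:
            return (min(right), min(right))
        return None

    def reverse(self) -> "LiftoverMap":
        """Map corrected coordinates back to the original genome.

        Inserted corrected bases are covered by no block and lift to None.
        """
        rev = LiftoverMap(
            orig_lengths=dict(self.corr_lengths),
            corr_lengths=dict(self.orig_lengths),
        )
        for chrom, blocks in self.blocks.items():
            rev.blocks[chrom] = sorted(
                (c, c + (e - s), s) for (s, e, c) in blocks
            )
        return rev

    @classmethod
    def identity(cls, genome: Genome) -> "LiftoverMap":
        m = cls()
        for chrom, seq in genome.chroms.items():
            n = len(seq)
            m.blocks[chrom] = [(1, n, 1)] if n else []
            m.orig_lengths[chrom] = n
            m.corr_lengths[chrom] = n
        return m

    def write_chain_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\torig_start\torig_end\tcorr_start\tcorr_end\n")
            for chrom, blocks in self.blocks.items():
                for s, e, c in blocks:
                    fh.write(f"{chrom}\t{s}\t{e}\t{c}\t{c + (e - s)}\n")


def apply_variants(
    genome: Genome, shared: VariantSet
) -> tuple[Genome, LiftoverMap, list[Variant]]:
    """Apply shared variants to the reference, producing a corrected genome.

    Variants are applied per chromosome in ascending coordinate order
    (ties broken by alt allele); a variant whose reference span overlaps an
    already-applied one is skipped and reported.  SNPs substitute in place;
    indels shift all downstream coordinates, which the returned LiftoverMap
    records.  The corrected length always equals the original length plus
    the summed length change of the applied variants.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in shared:
        if v.chrom not in genome.chroms:
            raise ValueError(f"variant on unknown chromosome {v.chrom!r}")
        by_chrom.setdefault(v.chrom, []).append(v)

    corrected = Genome(label="corrected")
    lmap = LiftoverMap()
    skipped: list[Variant] = []
    for chrom, seq in genome.chroms.items():
        n = len(seq)
        lmap.orig_lengths[chrom] = n
        parts: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        last_end = 0  # 1-based end of the last consumed reference base
        corr_cursor = 1
        for v in sorted(by_chrom.get(chrom, []), key=lambda v: (v.pos, v.alt)):
            if seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
                raise ValueError(
                    f"ref mismatch applying {chrom}:{v.pos} {v.ref}>{v.alt}"
                )
            if v.pos <= last_end:
                skipped.append(v)
                continue
            gap = seq[last_end : v.pos - 1]
            if gap:
                blocks.append((last_end + 1, v.pos - 1, corr_cursor))
                parts.append(gap)
                corr_cursor += len(gap)
            parts.append(v.alt)
            m = min(len(v.ref), len(v.alt))
            blocks.append((v.pos, v.pos + m - 1, corr_cursor))
            corr_cursor += len(v.alt)
            last_end = v.pos + len(v.ref) - 1
        tail = seq[last_end:]
        if tail:
            blocks.append((last_end + 1, n, corr_cursor))
            parts.append(tail)
            corr_cursor += len(tail)
        corrected.chroms[chrom] = "".join(parts)
        lmap.blocks[chrom] = blocks
        lmap.corr_lengths[chrom] = corr_cursor - 1
    return corrected, lmap, skipped


def lift_position(lmap: LiftoverMap, chrom: str, pos: int):
    """Functional wrapper around LiftoverMap.lift."""
    return lmap.lift(chrom, pos)


@dataclass(frozen=True)
class NewSite:
    """A corrected-genome site absent from the original reference."""

    site: OffTargetSite
    original_interval: tuple[int, int] | None  # 1-based inclusive, original genome
    reason: str  # pam_created | mismatch_reduced | sequence_shifted


@dataclass
class NewSiteReport:
    new_sites: list[NewSite]
    all_corrected_sites: list[OffTargetSite]

    def per_guide_class_counts(self, guide_ids, pam_classes) -> dict:
        counts = {g: {c: 0 for c in pam_classes} for g in guide_ids}
        for ns in self.new_sites:
            counts[ns.site.sgrna_id][ns.site.pam_class] += 1
        return counts


def _extract_footprint(seq: str, start: int, length: int, strand: str) -> str:
    frag = seq[start : start + length]
    return frag if strand == "+" else reverse_complement(frag)


def find_new_sites(
    original_sites: list[OffTargetSite],
    corrected_genome: Genome,
    original_genome: Genome,
    guides: list[GuideRNA],
    params: SearchParams,
    lmap: LiftoverMap,
) -> NewSiteReport:
    """Sites present in the corrected genome with no original counterpart.

    A corrected-genome site is new iff no original site with the same guide
    and strand lifts to an overlapping footprint interval.  Each new site
    is tagged by what the cultivar variation changed at the lifted-back
    locus: a PAM that became valid (pam_created), a mismatch count that
    dropped within tolerance (mismatch_reduced), or a footprint disrupted
    by an indel (sequence_shifted).
    """
    spacer_len = {g.id: len(g.spacer) for g in guides}
    spacers = {g.id: g.spacer for g in guides}
    lifted: dict[tuple, list[tuple[int, int]]] = {}
    for s in original_sites:
        fs, fe = s.footprint  # 0-based half-open
        iv = lmap.lift_interval(s.chrom, fs + 1, fe)
        if iv is not None:
            lifted.setdefault((s.sgrna_id, s.chrom, s.strand), []).append(iv)

    rev = lmap.reverse()
    corrected_sites: list[OffTargetSite] = []
    for g in guides:
        corrected_sites.extend(find_offtarget_sites(corrected_genome, g, params))

    new: list[NewSite] = []
    for s in corrected_sites:
        fs, fe = s.footprint  # corrected coordinates, 0-based half-open
        overlaps = any(
            not (e < fs + 1 or b > fe)
            for (b, e) in lifted.get((s.sgrna_id, s.chrom, s.strand), [])
        )
        if overlaps:
            continue
        orig_iv = rev.lift_interval(s.chrom, fs + 1, fe)
        L = spacer_len[s.sgrna_id]
        reason = "sequence_shifted"
        if orig_iv is not None and orig_iv[1] - orig_iv[0] == fe - fs - 1:
            oseq = original_genome.chroms[s.chrom]
            footprint = _extract_footprint(oseq, orig_iv[0] - 1, L + 3, s.strand)
            orig_pam = footprint[L:]
            if (
                classify_pam(orig_pam) is None
                or classify_pam(orig_pam) not in params.pam_classes
            ):
                reason = "pam_created"
            else:
                n_mm, _ = count_mismatches(
                    spacers[s.sgrna_id], footprint[:L], params.ambiguous_matches_all
                )
                if n_mm > params.max_mismatches:
                    reason = "mismatch_reduced"
        new.append(NewSite(site=s, original_interval=orig_iv, reason=reason))
    return NewSiteReport(new_sites=new, all_corrected_sites=corrected_sites)
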