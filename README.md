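# casaudit

Whole-genome off-target audit for CRISPR/Cas9-edited plant lines.

When an edited plant is whole-genome sequenced alongside wild-type (WT)
regenerants, almost every variant it carries is either cultivar variation
(the transformed cultivar differs from the reference assembly by millions of
SNPs and indels) or tissue-culture background — not Cas9 activity. `casaudit`
implements the bookkeeping that isolates the handful of candidate off-target
mutations from that noise:

1. **Site enumeration.** For each ~20-nt sgRNA spacer *s*, scan both strands
   of the genome for protospacers *p* with Hamming distance
   d(*s*, *p*) ≤ *k* (default *k* = 5) followed by a PAM of class NGG, NAG
   or NGA (first base unconstrained, classes decided by bases 2–3).
2. **Variant set algebra.** Per-line VCFs are quality-filtered
   (QUAL > 20, INFO/DP > 4, MQ > 30, strict), left-normalized, and treated
   as sets keyed on (chrom, pos, ref, alt). The **core** set is the
   intersection of all WT lines (cultivar-vs-reference variation); a line's
   **private** set is its variants minus the union of all WT sets.
3. **Off-target calling.** A private variant whose reference span (anchor
   base for insertions) falls inside a candidate site's protospacer+PAM
   (core zone) is a candidate off-target mutation; variants within ±100 bp
   are reported as flank-zone context. On-target mutations at 0-mismatch
   sites are typed as +k insertions / −k deletions.
4. **Cultivar correction.** Applying the core set to the reference yields a
   "corrected" genome with an indel-aware liftover map; re-running the site
   search there reveals sites newly created by cultivar variation
   (tagged `pam_created`, `mismatch_reduced` or `sequence_shifted`).

A synthetic-data module generates small genomes, multi-line cohorts with
shared/private variant structure, and planted edits with a truth table, so
the whole pipeline is testable without any sequencing data.

## Worked example

```python
import pathlib
import casaudit as ca
from casaudit.simulate import write_fixture

fx = ca.make_planted_fixture(seed=1)         # 50-kb genome, 3 WT + 2 edited
d = pathlib.Path("demo")
write_fixture(d, fx.genome, fx.cohort, fx.guides, fx.truth)
res = ca.run_audit(
    d / "genome.fa",
    sorted(d.glob("WT_*.vcf")),
    sorted(d.glob("ED_*.vcf")),
    fx.guides,
    gff=d / "genes.gff3",
)
print(res.offtarget_matrix.to_string(index=False))
print(res.on_target_table.to_string(index=False))
```

prints

```
line  sgrna NGG NAG NGA
ED_1 sgRNA1 0/2 0/0 0/0
ED_1 sgRNA2 0/1 0/0 0/0
ED_2 sgRNA1 1/2 0/0 0/0
ED_2 sgRNA2 0/1 0/0 0/0

line  sgrna chrom   pos mutation  dv  dp
ED_1 sgRNA1  chr1  5770       +1  17  35
ED_2 sgRNA2  chr1 20064       -3   6  13
```

Each off-target matrix cell is `mutations/sites`: the number of distinct
core-zone private variants over the number of candidate sites for that
(guide, PAM class). The fixture planted one off-target insertion in line
ED_2 at a 3-mismatch site of sgRNA1 — the single nonzero numerator — plus a
+1 and a −3 on-target edit, which appear in the on-target table with their
supporting-read counts (DV out of DP). `ca.write_report(res, "out/")` writes
the matrices, per-line variant counts, region annotation, per-hit records
and new-site table as TSV plus a JSON bundle.

The same pipeline runs from the shell:

```bash
audit sim --out fixture --seed 1
audit search --genome fixture/genome.fa --guides fixture/guides.tsv --out sites.bed
audit run --genome fixture/genome.fa --wt WT_1.vcf --wt WT_2.vcf --wt WT_3.vcf \
          --edited ED_1.vcf --guides fixture/guides.tsv --out report/
```

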