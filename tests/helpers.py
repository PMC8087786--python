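"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: plain string scans and
string edits only.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pam_class_of(pam: str) -> str | None:
    if "N" in pam:
        return None
    return {"GG": "NGG", "AG": "NAG", "GA": "NGA"}.get(pam[1:])


def naive_site_scan(chroms: dict[str, str], spacer: str, max_mm: int,
                    pam_classes=("NGG", "NAG", "NGA")) -> set[tuple]:
    """Every (chrom, start, strand, n_mm, pam_class) by testing all windows.

    ``start`` is the 0-based forward-strand start of the spacer+PAM
    footprint, matching the package's coordinate convention.
    """
    L = len(spacer)
    found = set()
    for chrom, seq in chroms.items():
        n = len(seq)
        for start in range(0, n - (L + 3) + 1):
            # forward strand
            proto = seq[start : start + L]
            pam = seq[start + L : start + L + 3]
            cls = pam_class_of(pam)
            if cls in pam_classes:
                mm = sum(1 for a, b in zip(spacer, proto) if a != b)
                if mm <= max_mm:
                    found.add((chrom, start, "+", mm, cls))
            # minus strand: footprint occupies the same forward interval
            frag = rc(seq[start : start + L + 3])
            proto_m, pam_m = frag[:L], frag[L:]
            cls_m = pam_class_of(pam_m)
            if cls_m in pam_classes:
                mm = sum(1 for a, b in zip(spacer, proto_m) if a != b)
                if mm <= max_mm:
                    found.add((chrom, start, "-", mm, cls_m))
    return found


def oracle_normalize(chrom_seq: str, pos: int, ref: str, alt: str,
                     window: int = 60):
    """Leftmost minimal representation via whole-window string comparison.

    Builds the reference and alternate haplotypes over a local window and
    trims the longest shared suffix, then the longest shared prefix
    (keeping an anchor base), which yields the left-aligned VCF record.
    Returns (pos, ref, alt) or None for a null variant.
    """
    w0 = max(0, pos - 1 - window)  # 0-based window start
    w1 = min(len(chrom_seq), pos - 1 + len(ref) + window)
    W = chrom_seq[w0:w1]
    Wp = (
        chrom_seq[w0 : pos - 1] + alt + chrom_seq[pos - 1 + len(ref) : w1]
    )
    if W == Wp:
        return None
    # longest common suffix
    s = 0
    while s < min(len(W), len(Wp)) and W[len(W) - 1 - s] == Wp[len(Wp) - 1 - s]:
        s += 1
    A, B = W[: len(W) - s], Wp[: len(Wp) - s]
    # longest common prefix
    p = 0
    while p < min(len(A), len(B)) and A[p] == B[p]:
        p += 1
    if len(A) == p or len(B) == p:
        # pure indel: keep one shared anchor base on the left
        p -= 1
    return (w0 + p + 1, A[p:] or chrom_seq[w0 + p], B[p:] or chrom_seq[w0 + p])


def apply_edits_oracle(seq: str, edits) -> str:
    """Apply (pos, ref, alt) edits to a string, right to left."""
    for pos, ref, alt in sorted(edits, reverse=True):
        assert seq[pos - 1 : pos - 1 + len(ref)] == ref
        seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    return seq
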