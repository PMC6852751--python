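"""In-silico PCR: primer binding-site search and amplicon prediction.

Used to verify junction-spanning primer pairs: a diagnostic pair amplifies
from the reconstructed mutant haplotype but not from wild type (or yields a
length shift equal to the insertion/deletion balance). Matching is sequence
identity with a mismatch allowance and a 3'-exactness rule; thermodynamics
are out of scope because verification is by product presence and length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import revcomp

__all__ = ["PrimerPair", "Amplicon", "find_sites", "predict_amplicons", "genotype_event"]


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd_seq: str
    rev_seq: str
    max_product: int = 5000

    def __post_init__(self) -> None:
        for seq in (self.fwd_seq, self.rev_seq):
            if not 15 <= len(seq) <= 35:
                raise ValueError(f"{self.name}: primer length must be 15-35 nt")
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.name}: primers must be over ACGT")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product; coordinates run from the forward primer's 5' base
    to the reverse primer's 5' base, 1-based inclusive (gel-length
    convention)."""

    template_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _mismatches(primer: str, window: str, limit: int, three_prime_exact: bool) -> int | None:
    if three_prime_exact and primer[-3:] != window[-3:]:
        return None
    mm = sum(1 for a, b in zip(primer, window) if a != b)
    return mm if mm <= limit else None


def find_sites(
    primer: str,
    template: str,
    max_mismatch: int = 1,
    require_3prime_exact: bool = True,
) -> list[tuple[int, str, int]]:
    """All (pos, strand, mismatches) binding sites of ``primer`` on both
    strands of ``template``; ``pos`` is the 1-based template coordinate of the
    primer's 5' base (leftmost base for '+', rightmost for '-')."""
    primer = primer.upper()
    template = template.upper()
    n, m = len(template), len(primer)
    out: list[tuple[int, str, int]] = []
    rc = revcomp(primer)
    for i in range(n - m + 1):
        window = template[i : i + m]
        mm = _mismatches(primer, window, max_mismatch, require_3prime_exact)
        if mm is not None:
            out.append((i + 1, "+", mm))
        # on the minus strand the primer reads 3'->5' left-to-right, so its
        # 3' end is the window's left edge and its 5' base is at i+m
        mm = _mismatches(primer, revcomp(window), max_mismatch, require_3prime_exact)
        if mm is not None:
            out.append((i + m, "-", mm))
    return out


def predict_amplicons(
    pair: PrimerPair,
    template_id: str,
    template: str,
    max_mismatch: int = 1,
    require_3prime_exact: bool = True,
) -> list[Amplicon]:
    """One amplicon per (fwd '+', rev '-') site combination with the forward
    5' base left of the reverse 5' base and product length <= max_product;
    sorted by length."""
    fwd = [
        s for s in find_sites(pair.fwd_seq, template, max_mismatch, require_3prime_exact)
        if s[1] == "+"
    ]
    rev = [
        s for s in find_sites(pair.rev_seq, template, max_mismatch, require_3prime_exact)
        if s[1] == "-"
    ]
    out = []
    min_len = len(pair.fwd_seq) + len(pair.rev_seq)
    for fp, _, fmm in fwd:
        for rp, _, rmm in rev:
            length = rp - fp + 1
            if min_len <= length <= pair.max_product:
                out.append(Amplicon(template_id, fp, rp, fmm, rmm))
    out.sort(key=lambda a: (a.length, a.start))
    return out


def genotype_event(
    pair: PrimerPair,
    wt_haplotype: dict[str, str],
    mutant_haplotype: dict[str, str],
    max_mismatch: int = 1,
    require_3prime_exact: bool = True,
) -> dict:
    """Predict products on wild-type and mutant templates.

    ``diagnostic`` is true iff the two amplicon sets differ in presence or
    length — the criterion a genotyping gel can score.
    """
    wt = [
        a
        for tid, seq in sorted(wt_haplotype.items())
        for a in predict_amplicons(pair, tid, seq, max_mismatch, require_3prime_exact)
    ]
    mut = [
        a
        for tid, seq in sorted(mutant_haplotype.items())
        for a in predict_amplicons(pair, tid, seq, max_mismatch, require_3prime_exact)
    ]
    diagnostic = sorted(a.length for a in wt) != sorted(a.length for a in mut)
    return {"wt": wt, "mutant": mut, "diagnostic": diagnostic}
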