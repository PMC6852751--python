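"""Gene-model impact of confirmed deletions.

Intersects each deletion interval with GFF3 gene models and reports base
pairs lost per feature class (five_prime_UTR, CDS, exon, intron, intergenic).
Intronic bp are inferred as gene-span bp not covered by exon-level features,
since GFF3 rarely encodes introns explicitly; the per-class counts always sum
to the deletion length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import EventRecord, GffFeature

__all__ = ["FeatureOverlap", "overlap_deletion"]

# when one base carries several annotations, count it once, highest first
_PRECEDENCE = ("CDS", "five_prime_UTR", "exon")

NO_KNOWN_GENE = "no known gene"


@dataclass
class FeatureOverlap:
    """Per-feature-class decomposition of one deletion."""

    event_label: str
    gene_ids: list[str] = field(default_factory=list)
    bp_by_type: dict[str, int] = field(default_factory=dict)
    total_del_bp: int = 0

    def describe(self) -> str:
        if self.total_del_bp == 0:
            genes = ", ".join(self.gene_ids) if self.gene_ids else NO_KNOWN_GENE
            return f"insertion without deletion; adjacent: {genes}"
        if not self.gene_ids:
            return NO_KNOWN_GENE
        parts = [
            f"{bp} bp {ftype}"
            for ftype, bp in self.bp_by_type.items()
            if bp and ftype not in ("intergenic",)
        ]
        return f"{', '.join(parts)} of {', '.join(self.gene_ids)}"


def _overlap_bp(a: int, b: int, c: int, d: int) -> int:
    """Overlap of 1-based inclusive intervals [a,b] and [c,d]."""
    return max(0, min(b, d) - max(a, c) + 1)


def overlap_deletion(
    event: EventRecord, features: list[GffFeature]
) -> FeatureOverlap:
    """Decompose the deleted interval of ``event`` over the gene models.

    Each deleted base is assigned to exactly one class with precedence
    CDS > five_prime_UTR > exon > intron > intergenic, so the per-class
    counts conserve the deletion length. Genes (``type == gene``) with at
    least one overlapping base are listed; zero-length deletions (pure
    insertions) list genes whose span contains or abuts the insertion point
    as adjacent context.
    """
    out = FeatureOverlap(event_label=event.label)
    del_len = event.del_len
    out.total_del_bp = del_len
    out.bp_by_type = {
        t: 0 for t in ("five_prime_UTR", "CDS", "exon", "intron", "intergenic")
    }
    chrom_feats = [f for f in features if f.seqid == event.chrom]
    if features and not chrom_feats:
        import logging

        logging.getLogger(__name__).warning(
            "event %s: contig %s absent from annotation; all bp intergenic",
            event.label,
            event.chrom,
        )
    genes = [f for f in chrom_feats if f.type == "gene"]
    if del_len == 0:
        point = event.del_end  # insertion sits between del_end and del_start
        out.gene_ids = sorted(
            {
                f.attributes.get("ID", f"{f.seqid}:{f.start}-{f.end}")
                for f in genes
                if f.start - 1 <= point <= f.end + 1
            }
        )
        return out

    a, b = event.del_start, event.del_end
    out.gene_ids = sorted(
        {
            f.attributes.get("ID", f"{f.seqid}:{f.start}-{f.end}")
            for f in genes
            if _overlap_bp(a, b, f.start, f.end) > 0
        }
    )
    # per-base class assignment via interval subtraction with precedence
    claimed = IntervalTree()  # half-open [start, end+1) over deleted bases

    def claim(ftype: str, start: int, end: int) -> None:
        s, e = max(a, start), min(b, end)
        if s > e:
            return
        tree = IntervalTree()
        tree[s : e + 1] = True
        for iv in claimed.overlap(s, e + 1):
            tree.chop(iv.begin, iv.end)
        for iv in tree:
            out.bp_by_type[ftype] += iv.end - iv.begin
            claimed[iv.begin : iv.end] = True

    for ftype in _PRECEDENCE:
        for f in chrom_feats:
            if f.type == ftype:
                claim(ftype, f.start, f.end)
    for g in genes:  # remaining bases inside a gene span are intronic
        claim("intron", g.start, g.end)
    assigned = sum(out.bp_by_type.values())
    out.bp_by_type["intergenic"] = del_len - assigned
    return out
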