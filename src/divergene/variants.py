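"""Allelic variant discovery, annotation, tallying and clustering.

Coordinates are 1-based.  A gene model lives in a TSS-relative frame:
position +1 is the transcription start, negative positions run upstream
through the promoter (no zero), the gene body covers exons and introns,
and a downstream enhancer region (DER) follows the gene end.  Genomic
positions use a Build-37-style chromosome coordinate for the TSS.

Indels follow a reference-line convention (here: relative to the
inbred reference strain C57BL/6J): an *insertion* is sequence present in
the LAB allele but absent from the HAB allele, a *deletion* the
reverse.  Indel events are left-aligned and a multi-base gap run counts
as one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = ["GeneModel", "diff_alleles", "annotate", "tally_variants",
           "cluster_scan", "coding_consequence", "read_variant_table",
           "write_variant_table"]


@dataclass
class GeneModel:
    """Locus structure used to annotate variants.

    ``exons``: ordered, non-overlapping (start, end) spans in the
    TSS-relative frame, first exon starting at +1.  ``promoter_bp`` and
    ``der_bp`` give the upstream / downstream footprint widths.
    ``utr5_end`` / ``utr3_start`` are mRNA-frame boundaries of the
    untranslated regions; ``cds_mrna`` is the (start, end) of the coding
    sequence in the spliced mRNA, and ``cds_sequence`` its nucleotides
    (required only for coding-consequence calls).
    """

    name: str
    chromosome: str
    strand: str = "+"
    tss_genomic: int = 1
    promoter_bp: int = 2500
    der_bp: int = 2000
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_mrna: tuple[int, int] | None = None
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon span reversed: ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = e
        if self.exons and self.exons[0][0] != 1:
            raise ValueError("first exon must start at TSS (+1)")

    # -- spans ------------------------------------------------------------
    @property
    def gene_end(self) -> int:
        return self.exons[-1][1]

    @property
    def promoter_span(self) -> tuple[int, int]:
        return (-self.promoter_bp, -1)

    @property
    def der_span(self) -> tuple[int, int]:
        return (self.gene_end + 1, self.gene_end + self.der_bp)

    def intron_span(self, k: int) -> tuple[int, int]:
        """Span of intron k (between exon k and exon k+1), 1-based k."""
        if not 1 <= k <= len(self.exons) - 1:
            raise ValueError(f"no intron {k}")
        return (self.exons[k - 1][1] + 1, self.exons[k][0] - 1)

    def span_of(self, region: str) -> tuple[int, int]:
        if region == "promoter":
            return self.promoter_span
        if region == "DER":
            return self.der_span
        if region == "gene":
            return (1, self.gene_end)
        kind, _, num = region.partition("-")
        if kind == "exon" and num:
            return self.exons[int(num) - 1]
        if kind == "intron" and num:
            return self.intron_span(int(num))
        raise ValueError(f"unknown region {region!r}")

    # -- coordinate arithmetic --------------------------------------------
    def rel_to_genomic(self, rel: int) -> int:
        if rel == 0:
            raise ValueError("TSS-relative coordinates have no zero")
        off = rel - 1 if rel > 0 else rel
        return self.tss_genomic + off if self.strand == "+" else self.tss_genomic - off

    def genomic_to_rel(self, pos: int) -> int:
        off = pos - self.tss_genomic if self.strand == "+" else self.tss_genomic - pos
        return off + 1 if off >= 0 else off

    def mrna_position(self, rel: int) -> int | None:
        """Offset in the spliced mRNA (1-based), or None if non-exonic."""
        acc = 0
        for s, e in self.exons:
            if s <= rel <= e:
                return acc + (rel - s) + 1
            acc += e - s + 1
        return None

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def region_of(self, rel: int) -> str:
        """Region label of a TSS-relative position.

        UTR labels take precedence over exon numbering; positions outside
        the promoter/gene/DER footprint are 'flanking'.
        """
        p_lo, p_hi = self.promoter_span
        if p_lo <= rel <= p_hi:
            return "promoter"
        d_lo, d_hi = self.der_span
        if d_lo <= rel <= d_hi:
            return "DER"
        for k, (s, e) in enumerate(self.exons, start=1):
            if s <= rel <= e:
                mpos = self.mrna_position(rel)
                if self.cds_mrna is not None:
                    if mpos < self.cds_mrna[0]:
                        return "5'UTR"
                    if mpos > self.cds_mrna[1]:
                        return "3'UTR"
                return f"exon-{k}"
            if k < len(self.exons) and e < rel < self.exons[k][0]:
                return f"intron-{k}"
        return "flanking"

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name, "chromosome": self.chromosome,
            "strand": self.strand, "tss_genomic": self.tss_genomic,
            "promoter_bp": self.promoter_bp, "der_bp": self.der_bp,
            "exons": [list(e) for e in self.exons],
            "cds_mrna": list(self.cds_mrna) if self.cds_mrna else None,
            "cds_sequence": self.cds_sequence,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["exons"] = [tuple(e) for e in doc.get("exons", [])]
        if doc.get("cds_mrna"):
            doc["cds_mrna"] = tuple(doc["cds_mrna"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# sequence comparison

def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5
    al.extend_gap_score = -1
    return al


def diff_alleles(seq_hab: str, seq_lab: str, anchor: int = 1) -> pd.DataFrame:
    """Globally align two allele sequences and list their differences.

    ``anchor`` is the coordinate of the first base of the HAB sequence;
    SNP positions are ``anchor + i`` for a mismatch at 0-based HAB index
    ``i``; indel events are anchored at the HAB base preceding the gap
    run.  Columns with N in either sequence are skipped.  Gap runs are
    single events: sequence present only in LAB is an insertion, present
    only in HAB a deletion (the reference-line convention).
    """
    seq_hab, seq_lab = seq_hab.upper(), seq_lab.upper()
    if not seq_hab or not seq_lab:
        raise ValueError("empty sequence")
    bad = set(seq_hab + seq_lab) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    aln = _aligner().align(seq_hab, seq_lab)[0]
    a, b = str(aln[0]), str(aln[1])
    rows = []
    i = 0  # 0-based index into seq_hab of the current column
    col = 0
    while col < len(a):
        ca, cb = a[col], b[col]
        if ca == "-":  # insertion: bases present only in LAB
            run = col
            while run < len(a) and a[run] == "-":
                run += 1
            ins = b[col:run].replace("N", "")
            if ins:
                rows.append(("insertion", anchor + i - 1, "-", b[col:run]))
            col = run
            continue
        if cb == "-":  # deletion: bases present only in HAB
            run = col
            while run < len(a) and b[run] == "-":
                run += 1
            rows.append(("deletion", anchor + i - 1, a[col:run], "-"))
            i += run - col
            col = run
            continue
        if ca != cb and ca != "N" and cb != "N":
            rows.append(("SNP", anchor + i, ca, cb))
        i += 1
        col += 1
    return pd.DataFrame(rows, columns=["type", "rel_position", "HAB", "LAB"])


# ---------------------------------------------------------------------------
# annotation, tallies, clusters

def annotate(variants: pd.DataFrame, model: GeneModel) -> pd.DataFrame:
    """Fill region, genomic and mRNA coordinates from a gene model.

    Input needs ``rel_position`` (TSS-relative) or ``genomic_position``.
    Idempotent and invariant to record order.
    """
    out = variants.copy()
    if "rel_position" not in out:
        if "genomic_position" not in out:
            raise ValueError("need rel_position or genomic_position")
        out["rel_position"] = [model.genomic_to_rel(p)
                               for p in out["genomic_position"]]
    rel = out["rel_position"].astype(int)
    out["genomic_position"] = [model.rel_to_genomic(p) for p in rel]
    out["location"] = [model.region_of(p) for p in rel]
    out["mrna_position"] = [model.mrna_position(p) for p in rel]
    return out


def tally_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of counts per (type, location) with margins.

    Margins appear as a 'total' row and column; they sum to the record
    count by construction.
    """
    if len(variants) == 0:
        return pd.DataFrame({"total": {"total": 0}})
    tab = pd.crosstab(variants["type"], variants["location"],
                      margins=True, margins_name="total")
    return tab


def _region_mask(location: pd.Series, region_filter: str | None) -> pd.Series:
    if region_filter is None:
        return pd.Series(True, index=location.index)
    if region_filter in ("intron", "introns"):
        return location.str.startswith("intron")
    if region_filter in ("exon", "exons"):
        return location.str.startswith("exon") | location.isin(["5'UTR", "3'UTR"])
    return location == region_filter


def cluster_scan(variants: pd.DataFrame, window_bp: int,
                 region_filter: str | None = None) -> pd.DataFrame:
    """Densest variant windows of a given width.

    Slides a half-open window [start, start + window_bp) anchored at
    each variant position (after optional region filtering) and returns
    the window(s) with maximal count, ties in position order.  The count
    is monotone non-decreasing in ``window_bp``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    sub = variants
    if region_filter is not None:
        if "location" not in variants:
            raise ValueError("region filtering needs annotated records")
        sub = variants[_region_mask(variants["location"], region_filter)]
    pos = np.sort(sub["rel_position"].to_numpy(int))
    if pos.size == 0:
        return pd.DataFrame(columns=["start", "end", "count"])
    counts = np.searchsorted(pos, pos + window_bp, side="left") - np.arange(pos.size)
    best = counts.max()
    hits = np.flatnonzero(counts == best)
    return pd.DataFrame({
        "start": pos[hits],
        "end": pos[hits] + window_bp - 1,
        "count": counts[hits],
    })


# ---------------------------------------------------------------------------
# coding consequences

def coding_consequence(variant: pd.Series | dict, model: GeneModel) -> str:
    """Consequence of a variant on the coding sequence.

    Exonic SNPs inside the CDS are translated under both alleles with
    the standard codon table: 'synonymous (Xxx)' or 'missense Xxx->Yyy'.
    CDS indels are reported as 'frame-affecting' without an amino-acid
    call; anything outside the CDS is 'non-coding'.
    """
    if model.cds_mrna is None or model.cds_sequence is None:
        raise ValueError("model lacks CDS definition/sequence")
    v = dict(variant)
    rel = int(v["rel_position"])
    mpos = model.mrna_position(rel)
    cds_lo, cds_hi = model.cds_mrna
    if mpos is None or not cds_lo <= mpos <= cds_hi:
        return "non-coding"
    if v["type"] != "SNP":
        return "frame-affecting"
    cds_off = mpos - cds_lo  # 0-based offset into CDS
    codon_idx = cds_off // 3
    in_codon = cds_off % 3
    codon = model.cds_sequence[codon_idx * 3: codon_idx * 3 + 3].upper()
    if len(codon) < 3:
        raise ValueError("CDS sequence shorter than CDS span")
    hab, lab = str(v["HAB"]).upper(), str(v["LAB"]).upper()
    if codon[in_codon] not in (hab, lab):
        raise ValueError(
            f"CDS base {codon[in_codon]} at mRNA {mpos} matches neither allele")
    codon_hab = codon[:in_codon] + hab + codon[in_codon + 1:]
    codon_lab = codon[:in_codon] + lab + codon[in_codon + 1:]
    aa_hab = seq3(str(Seq(codon_hab).translate()))
    aa_lab = seq3(str(Seq(codon_lab).translate()))
    if aa_hab == aa_lab:
        return f"synonymous ({aa_hab})"
    return f"missense {aa_hab}->{aa_lab}"


# ---------------------------------------------------------------------------
# table IO

VARIANT_COLUMNS = ["type", "genomic_position", "HAB", "LAB", "location",
                   "rel_position", "mrna_position", "snp_id"]


def read_variant_table(path) -> pd.DataFrame:
    """Read the variant TSV dialect (columns mirroring the catalogue:
    type, genomic_position, HAB, LAB, location, rel_position,
    mrna_position, snp_id).  The table's own location labels are
    preserved, not re-derived."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
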