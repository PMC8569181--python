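"""Phosphorothioate (PT) site arithmetic: motif scanning, modification
frequencies, site-to-gene mapping, and coupling with differential expression.

PT modification in the GAAC/GTTC consensus places the sulfur on the
phosphodiester 3' of the G, giving the d(GpsA) and d(GpsT) dinucleotides. The
consensus is a double-stranded pseudo-palindrome: every 5'-GAAC-3' on one
strand faces a 5'-GTTC-3' on the other at the same locus, so motif totals can
be counted per reference strand, over both strands, or as double-stranded
pairs — the three conventions exposed by :func:`motif_totals`.

Modification is partial: only a few percent of consensus motifs carry the
modification at any time, which is why observed site counts are compared
against total motif counts (:func:`modified_fraction`) and expressed per 10^6
nucleotides (:func:`modification_frequency`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .cooccur_stats import students_t_test
from .genome_io import GenomeRecord, ValidationError

__all__ = [
    "MOTIFS",
    "MOTIF_CLASS",
    "DINUCLEOTIDE",
    "PtSite",
    "PtFrequency",
    "scan_motifs",
    "motif_totals",
    "modification_frequency",
    "modified_fraction",
    "convention_report",
    "map_sites_to_features",
    "deg_pt_coupling",
]

MOTIFS = ("GAAC", "GTTC")
MOTIF_CLASS = {"GAAC": "GpsAAC", "GTTC": "GpsTTC"}
DINUCLEOTIDE = {"GpsAAC": "d(GpsA)", "GpsTTC": "d(GpsT)"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PtSite:
    replicon_id: str
    position: int  # 1-based position of the modified G on the given strand
    strand: str
    motif_class: str  # GpsAAC | GpsTTC

    @property
    def dinucleotide(self) -> str:
        return DINUCLEOTIDE[self.motif_class]


@dataclass(frozen=True)
class PtFrequency:
    count: int
    denominator_nt: int
    freq_per_1e6_nt: float
    per_molecule: float | None = None


def scan_motifs(
    sequence: str, motifs: tuple[str, ...] = MOTIFS
) -> list[tuple[int, str]]:
    """All (1-based position, motif) matches on the reference strand.

    Overlapping matches are reported; N never matches. A GAAC match at
    position i is simultaneously a GTTC locus on the complementary strand —
    use :func:`motif_totals` for double-stranded accounting.
    """
    seq = sequence.upper()
    out: list[tuple[int, str]] = []
    for motif in motifs:
        pat = re.compile(f"(?={re.escape(motif)})")
        out.extend((m.start() + 1, motif) for m in pat.finditer(seq))
    out.sort()
    return out


def motif_totals(sequence: str) -> dict[str, dict[str, int]]:
    """Motif totals under the three double-strand accounting conventions.

    * ``reference_strand``: per-class counts on the given strand only;
    * ``both_strands``: per-class counts summed over the strand and its
      reverse complement (each ds locus counted once per strand);
    * ``ds_pair``: one count per double-stranded consensus locus (a reference
      GAAC and the facing GTTC are the same pair), identical for both classes.
    """
    seq = sequence.upper()
    ref = {m: sum(1 for _ in re.finditer(f"(?={m})", seq)) for m in MOTIFS}
    rc = reverse_complement(seq)
    rev = {m: sum(1 for _ in re.finditer(f"(?={m})", rc)) for m in MOTIFS}
    n_pairs = ref["GAAC"] + ref["GTTC"]
    return {
        "reference_strand": {"GAAC": ref["GAAC"], "GTTC": ref["GTTC"]},
        "both_strands": {
            "GAAC": ref["GAAC"] + rev["GAAC"],
            "GTTC": ref["GTTC"] + rev["GTTC"],
        },
        "ds_pair": {"GAAC": n_pairs, "GTTC": n_pairs},
    }


def modification_frequency(
    count: int,
    denominator_nt: int,
    molecule_length_bp: int | None = None,
    double_stranded: bool = True,
) -> PtFrequency:
    """Modification frequency per 10^6 nt, optionally per molecule.

    For a double-stranded molecule of L bp the per-molecule count uses 2L nt
    (both strands carry the modification context); single-stranded uses L.
    """
    if denominator_nt <= 0:
        raise ValidationError("denominator_nt must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    freq = count / denominator_nt * 1e6
    per_molecule = None
    if molecule_length_bp is not None:
        molecule_nt = 2 * molecule_length_bp if double_stranded else molecule_length_bp
        per_molecule = freq / 1e6 * molecule_nt
    return PtFrequency(count, denominator_nt, freq, per_molecule)


def modified_fraction(modified_count: int, total_motif_count: int) -> float:
    """Percentage of consensus motifs that carry the modification."""
    if total_motif_count <= 0:
        raise ValidationError("total_motif_count must be positive")
    if not (0 <= modified_count <= total_motif_count):
        raise ValidationError("need 0 <= modified <= total")
    return 100.0 * modified_count / total_motif_count


def convention_report(
    sequence: str, modified_counts: dict[str, int]
) -> pd.DataFrame:
    """Modified-motif percentages under every denominator convention.

    ``modified_counts`` maps motif class (GpsAAC/GpsTTC) to the number of
    modified sites observed. One row per (convention, class) with the total
    and the percentage — used to identify which accounting convention a
    reported percentage was computed under.
    """
    totals = motif_totals(sequence)
    rows = []
    for conv, t in totals.items():
        for motif in MOTIFS:
            cls = MOTIF_CLASS[motif]
            mod = modified_counts.get(cls, 0)
            rows.append(
                {
                    "convention": conv,
                    "motif_class": cls,
                    "modified": mod,
                    "total": t[motif],
                    "percent": modified_fraction(mod, t[motif]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site-to-gene mapping
# ---------------------------------------------------------------------------


def map_sites_to_features(
    sites: pd.DataFrame, genome: GenomeRecord
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign PT sites to every CDS whose interval contains them.

    ``sites`` uses 1-based reference-strand positions. A site falling in
    overlapping CDS is counted in each of them; sites in no CDS are returned
    in the intergenic table. Returns ``(per_gene, intergenic)`` where
    ``per_gene`` has one row per CDS of the genome (zero counts included).
    """
    lengths = {r.replicon_id: r.length for r in genome.replicons}
    trees: dict[str, IntervalTree] = {}
    for f in genome.features:
        trees.setdefault(f.replicon_id, IntervalTree()).addi(f.start, f.end, f.gene_id)

    counts: dict[str, dict[str, int]] = {
        f.gene_id: {"d(GpsA)": 0, "d(GpsT)": 0} for f in genome.features
    }
    intergenic_rows = []
    for row in sites.itertuples(index=False):
        rep = str(row.replicon_id)
        if rep not in lengths:
            raise ValidationError(f"site on unknown replicon {rep}")
        pos0 = int(row.position) - 1
        if not (0 <= pos0 < lengths[rep]):
            raise ValidationError(
                f"site position {row.position} beyond replicon {rep} "
                f"length {lengths[rep]}"
            )
        dinuc = DINUCLEOTIDE[str(row.motif_class)]
        overlapping = trees.get(rep, IntervalTree())[pos0]
        if overlapping:
            for iv in overlapping:
                counts[iv.data][dinuc] += 1
        else:
            intergenic_rows.append(
                {
                    "replicon_id": rep,
                    "position": int(row.position),
                    "strand": str(row.strand),
                    "motif_class": str(row.motif_class),
                }
            )
    per_gene = pd.DataFrame(
        {
            "gene_id": list(counts),
            "n_gpsa": [c["d(GpsA)"] for c in counts.values()],
            "n_gpst": [c["d(GpsT)"] for c in counts.values()],
        }
    )
    per_gene["n_pt_sites"] = per_gene["n_gpsa"] + per_gene["n_gpst"]
    return per_gene, pd.DataFrame(intergenic_rows)


# ---------------------------------------------------------------------------
# DEG / PT coupling
# ---------------------------------------------------------------------------


def deg_pt_coupling(
    de_table: pd.DataFrame,
    per_gene_site_counts: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
) -> dict:
    """Couple differential expression with per-gene PT-site counts.

    A gene is a DEG when ``fdr < fdr_max`` and its linear fold change exceeds
    ``fc_min`` in either direction (``|log2fc| > log2(fc_min)``). The report
    compares the proportion of DEGs vs non-DEGs containing >= 1 PT site and
    runs a pooled two-sided Student's t on mean site counts. Genes missing
    from the site table count zero sites.
    """
    import numpy as np

    df = de_table.copy()
    df["is_deg"] = (df["fdr"] < fdr_max) & (df["log2fc"].abs() > np.log2(fc_min))
    merged = df.merge(
        per_gene_site_counts[["gene_id", "n_pt_sites"]], on="gene_id", how="left"
    )
    merged["n_pt_sites"] = merged["n_pt_sites"].fillna(0).astype(int)

    deg = merged[merged["is_deg"]]
    non = merged[~merged["is_deg"]]
    report: dict[str, object] = {
        "n_genes": int(len(merged)),
        "n_deg": int(len(deg)),
        "n_non_deg": int(len(non)),
        "deg_with_pt_percent": (
            float(100.0 * (deg["n_pt_sites"] >= 1).mean()) if len(deg) else None
        ),
        "non_deg_with_pt_percent": (
            float(100.0 * (non["n_pt_sites"] >= 1).mean()) if len(non) else None
        ),
        "mean_pt_sites_deg": float(deg["n_pt_sites"].mean()) if len(deg) else None,
        "mean_pt_sites_non_deg": float(non["n_pt_sites"].mean()) if len(non) else None,
    }
    if len(deg) >= 2 and len(non) >= 2:
        t, dof, p = students_t_test(deg["n_pt_sites"], non["n_pt_sites"])
        report["t_statistic"], report["t_df"], report["t_p_value"] = t, dof, p
    else:
        report["t_statistic"] = report["t_df"] = report["t_p_value"] = None
    return report
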