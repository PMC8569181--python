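"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes — they
are first-class, tested code, not fixtures:

* :func:`simulate_panel` builds per-genus genome panels with dnd clusters
  planted as adjacent CDS runs and per-genome prophage counts drawn from a
  log-linear Poisson model, ``count ~ Poisson(lambda * exp(beta * I[dnd]))``;
  ``beta < 0`` encodes a negative dnd-prophage dependence;
* :func:`simulate_hit_table` wraps planted assignments in a realistic
  homology-hit table (true hits pass the detection thresholds, decoys fail at
  least one) so that detection recovers the planted truth exactly;
* :func:`simulate_prophage_proteins` emits per-protein viral hits at a chosen
  purity for the majority-rules assignment;
* :func:`simulate_sequence_with_motifs` builds a motif-free background by
  rejection sampling, plants an exact number of GAAC/GTTC motifs, and marks a
  chosen fraction as modified PT sites;
* :func:`simulate_competition` inverts the serial-transfer doubling model for
  a target relative fitness and adds binomial colony sampling;
* :func:`simulate_de_table` plants differentially expressed genes that satisfy
  the FDR/fold-change thresholds by construction, with optional PT-site
  enrichment among DEGs.

Every generator is a pure function of its parameters and seed: identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dnd_detect import CLUSTER_FAMILIES
from .fitness import doublings
from .genome_io import GeneFeature, GenomeRecord, HomologyHit, ProphageRegion, Replicon
from .pt_sites import MOTIF_CLASS, MOTIFS, scan_motifs

__all__ = [
    "PanelSpec",
    "SimulatedPanel",
    "simulate_panel",
    "simulate_hit_table",
    "simulate_prophage_proteins",
    "simulate_sequence_with_motifs",
    "simulate_competition",
    "simulate_de_table",
]

GENE_LENGTH = 900
GENE_SPACING = 1000  # start-to-start distance in bp


@dataclass
class PanelSpec:
    """Study conditions for a synthetic genome panel.

    Defaults follow the structure of a well-sampled bacterial genus panel: one
    genus of 500 complete genomes, a dndBCDE prevalence of 0.18, prophage
    counts at a mean of 2 per genome, and a strong negative dependence of
    prophage counts on dnd presence (log-rate shift beta = -1.5).
    """

    seed: int
    n_genera: int = 1
    genomes_per_genus: int = 500
    genes_per_genome: int = 60
    dnd_cluster_prevalence: dict[str, float] = field(
        default_factory=lambda: {"dndBCDE": 0.18}
    )
    prophage_rate: float = 2.0
    dependence_beta: float = -1.5

    def __post_init__(self) -> None:
        if self.prophage_rate < 0:
            raise ValueError("prophage_rate must be >= 0")
        for c, p in self.dnd_cluster_prevalence.items():
            if c not in CLUSTER_FAMILIES:
                raise ValueError(f"unknown cluster type {c}")
            if not (0 <= p <= 1):
                raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class SimulatedPanel:
    spec: PanelSpec
    genomes: list[GenomeRecord]
    taxonomy: pd.DataFrame
    truth: pd.DataFrame  # genome_id, genus, cluster flags, dnd_any, n_prophages
    assignments: pd.DataFrame  # genome_id, gene_id, family (planted dnd genes)

    @property
    def prophage_counts(self) -> pd.DataFrame:
        return self.truth.rename(columns={})[["genome_id", "n_prophages"]]


def simulate_panel(spec: PanelSpec, include_genomes: bool = True) -> SimulatedPanel:
    """Generate a genome panel with planted dnd clusters and prophage counts.

    With ``include_genomes=False`` only the seeded truth tables are produced
    (identical draws), which keeps large replicate studies cheap; the genome
    records then stay empty.
    """
    rng = np.random.default_rng(spec.seed)
    # separate stream for cosmetic genome structure (strands), so the truth
    # tables are identical whether or not genomes are materialised
    rng_struct = np.random.default_rng([spec.seed, 1])
    n_genes = spec.genes_per_genome
    cluster_sizes = {c: len(f) for c, f in CLUSTER_FAMILIES.items()}
    total_planted = sum(
        cluster_sizes[c] for c, p in spec.dnd_cluster_prevalence.items() if p > 0
    )
    if total_planted and total_planted * 2 > n_genes:
        raise ValueError(
            f"cannot plant clusters totalling {total_planted} genes in a "
            f"{n_genes}-gene genome"
        )

    genomes: list[GenomeRecord] = []
    tax_rows, truth_rows, assign_rows = [], [], []
    for gi in range(spec.n_genera):
        genus = f"Genus{gi:02d}"
        for gj in range(spec.genomes_per_genus):
            genome_id = f"{genus}_g{gj:04d}"
            planted: dict[str, bool] = {}
            for ctype in CLUSTER_FAMILIES:
                prev = spec.dnd_cluster_prevalence.get(ctype, 0.0)
                planted[ctype] = bool(rng.random() < prev) if prev > 0 else False
            planted_families: list[tuple[int, str]] = []  # (ordinal, family)
            present_clusters = [c for c in CLUSTER_FAMILIES if planted[c]]
            pos = 0
            for idx, ctype in enumerate(present_clusters):
                k = cluster_sizes[ctype]
                # leave room (plus one spacer CDS) for every later cluster
                tail = sum(
                    cluster_sizes[c] + 1 for c in present_clusters[idx + 1:]
                )
                high = n_genes - k - tail
                start = int(rng.integers(pos, high + 1)) if high > pos else pos
                fams = list(CLUSTER_FAMILIES[ctype])
                rng.shuffle(fams)
                for off, fam in enumerate(fams):
                    planted_families.append((start + off, fam))
                pos = start + k + 1
            dnd_any = any(planted.values())
            lam = spec.prophage_rate * float(
                np.exp(spec.dependence_beta * (1 if dnd_any else 0))
            )
            n_prophages = int(rng.poisson(lam)) if lam > 0 else 0

            tax_rows.append(
                {
                    "genome_id": genome_id,
                    "phylum": "SynthPhylum",
                    "class": "SynthClass",
                    "order": "SynthOrder",
                    "family": "SynthFamily",
                    "genus": genus,
                    "species": f"{genus} sp{gj % 5}",
                }
            )
            truth_row = {"genome_id": genome_id, "genus": genus}
            for ctype in CLUSTER_FAMILIES:
                truth_row[ctype] = planted[ctype]
            truth_row["dnd_any"] = dnd_any
            truth_row["n_prophages"] = n_prophages
            truth_rows.append(truth_row)

            if include_genomes:
                features = []
                fam_at = dict(planted_families)
                for ordn in range(n_genes):
                    gene_id = f"{genome_id}_p{ordn:04d}"
                    features.append(
                        GeneFeature(
                            gene_id=gene_id,
                            replicon_id="chrom",
                            start=ordn * GENE_SPACING,
                            end=ordn * GENE_SPACING + GENE_LENGTH,
                            strand="+" if rng_struct.random() < 0.5 else "-",
                            ordinal=ordn,
                        )
                    )
                    if ordn in fam_at:
                        assign_rows.append(
                            {
                                "genome_id": genome_id,
                                "gene_id": gene_id,
                                "family": fam_at[ordn],
                            }
                        )
                genomes.append(
                    GenomeRecord(
                        genome_id=genome_id,
                        replicons=[
                            Replicon("chrom", n_genes * GENE_SPACING, False)
                        ],
                        features=features,
                        taxonomy={"genus": genus},
                    )
                )
    return SimulatedPanel(
        spec=spec,
        genomes=genomes,
        taxonomy=pd.DataFrame(tax_rows),
        truth=pd.DataFrame(truth_rows),
        assignments=pd.DataFrame(
            assign_rows, columns=["genome_id", "gene_id", "family"]
        ),
    )


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------


def simulate_hit_table(
    assignments: pd.DataFrame,
    seed: int,
    decoy_rate: float = 0.0,
    decoy_pool: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Hit table (outfmt-6 columns + qlen) recovering planted assignments.

    True hits are drawn to pass the detection thresholds comfortably
    (e <= 1e-12, qcov >= 0.6); decoys (``decoy_rate`` per true hit, drawn for
    genes in ``decoy_pool``) fail the e-value or the coverage threshold.
    Returns the table and the subject->family map.
    """
    rng = np.random.default_rng(seed)
    rows = []
    family_map: dict[str, str] = {}
    all_families = sorted({f for fams in CLUSTER_FAMILIES.values() for f in fams})
    for fam in all_families:
        family_map[f"{fam}_ref"] = fam

    def _row(query, subject, evalue, qcov, bitscore):
        qlen = int(rng.integers(200, 500))
        aln = max(1, int(round(qcov * qlen)))
        return {
            "qseqid": query, "sseqid": subject,
            "pident": round(float(rng.uniform(30, 95)), 1),
            "length": aln, "mismatch": 0, "gapopen": 0,
            "qstart": 1, "qend": aln, "sstart": 1, "send": aln,
            "evalue": evalue, "bitscore": round(bitscore, 1), "qlen": qlen,
        }

    for rec in assignments.itertuples(index=False):
        evalue = 10.0 ** float(rng.uniform(-40, -12))
        qcov = float(rng.uniform(0.6, 1.0))
        bitscore = float(rng.uniform(120, 400))
        rows.append(_row(rec.gene_id, f"{rec.family}_ref", evalue, qcov, bitscore))

    n_decoys = int(round(decoy_rate * len(assignments)))
    pool = decoy_pool or list(assignments["gene_id"])
    for _ in range(n_decoys):
        query = pool[int(rng.integers(len(pool)))]
        fam = all_families[int(rng.integers(len(all_families)))]
        if rng.random() < 0.5:  # fail the e-value cut-off
            evalue = 10.0 ** float(rng.uniform(-9, -3))
            qcov = float(rng.uniform(0.6, 1.0))
        else:  # fail the coverage cut-off
            evalue = 10.0 ** float(rng.uniform(-40, -12))
            qcov = float(rng.uniform(0.05, 0.45))
        rows.append(_row(query, f"{fam}_ref", evalue, qcov, rng.uniform(120, 400)))

    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
    ]
    return pd.DataFrame(rows, columns=cols), family_map


def hits_from_frame(df: pd.DataFrame, family_map: dict[str, str]) -> list[HomologyHit]:
    """In-memory counterpart of ``read_hits_tsv`` for simulated tables."""
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            subject_family=family_map.get(str(r.sseqid), "unknown"),
            pident=float(r.pident),
            aln_length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            qlen=int(r.qlen),
            qcov=int(r.length) / int(r.qlen),
        )
        for r in df.itertuples(index=False)
    ]


def simulate_prophage_proteins(
    region: ProphageRegion,
    true_family: str,
    purity: float,
    seed: int,
    other_families: tuple[str, ...] = ("Myoviridae", "Podoviridae"),
) -> list[HomologyHit]:
    """Per-protein viral hits at the given purity for majority-rule testing.

    ``round(purity * n)`` proteins get a qualifying best hit (bitscore >= 50)
    to ``true_family``; the rest either lack hits or carry sub-threshold hits
    scattered over ``other_families``, so the expected assignment is
    ``true_family`` exactly when purity >= 0.5.
    """
    if not (0 <= purity <= 1):
        raise ValueError("purity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(region.protein_ids)
    n_true = int(round(purity * n))
    hits: list[HomologyHit] = []

    def _hit(pid, family, bitscore):
        return HomologyHit(
            query_id=pid,
            subject_id=f"{family}_vref",
            subject_family=family,
            pident=float(rng.uniform(30, 90)),
            aln_length=150,
            evalue=10.0 ** float(rng.uniform(-30, -5)),
            bitscore=float(bitscore),
            qlen=200,
            qcov=0.75,
        )

    for i, pid in enumerate(region.protein_ids):
        if i < n_true:
            hits.append(_hit(pid, true_family, rng.uniform(50, 300)))
        elif rng.random() < 0.5:
            fam = other_families[int(rng.integers(len(other_families)))]
            hits.append(_hit(pid, fam, rng.uniform(20, 49.5)))
        # else: no hit at all
    return hits


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------


def simulate_sequence_with_motifs(
    length: int,
    motif_density: float,
    modified_fraction: float,
    seed: int,
    replicon_id: str = "chrom",
    max_rounds: int = 200,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Sequence with an exact number of planted GAAC/GTTC motifs.

    ``round(motif_density * length)`` motifs (split evenly between classes,
    GAAC getting the odd one) are planted at non-overlapping positions at
    least 8 bp apart; the background is scrubbed of accidental motifs by
    iterative resampling, so a scan recovers exactly the planted loci.
    ``round(modified_fraction * n_class)`` planted motifs per class are
    emitted as modified PT sites (reference strand, position of the G).

    Returns ``(sequence, sites_table, planted_table)``.
    """
    n_planted = int(round(motif_density * length))
    if n_planted * 8 > length:
        raise ValueError("cannot place motifs without overlap: density too high")
    if not (0 <= modified_fraction <= 1):
        raise ValueError("modified_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(alphabet, size=length).astype("U1")

    # choose planted starts on an 8-bp grid to guarantee spacing
    n_slots = length // 8
    if n_planted > n_slots:
        raise ValueError("cannot place motifs without overlap: density too high")
    slots = rng.choice(n_slots, size=n_planted, replace=False)
    starts = np.sort(slots * 8)  # 0-based motif start positions
    n_gaac = (n_planted + 1) // 2
    motif_of: dict[int, str] = {}
    order = rng.permutation(n_planted)
    for rank, idx in enumerate(order):
        motif_of[int(starts[idx])] = "GAAC" if rank < n_gaac else "GTTC"

    planted_pos = set()
    for s, m in motif_of.items():
        seq[s:s + 4] = list(m)
        planted_pos.update(range(s, s + 4))

    # scrub accidental motifs (background or junction-created)
    for _ in range(max_rounds):
        text = "".join(seq)
        accidental = [
            (pos - 1)
            for pos, _m in scan_motifs(text)
            if (pos - 1) not in motif_of
        ]
        if not accidental:
            break
        for s in accidental:
            mutable = [i for i in range(s, s + 4) if i not in planted_pos]
            i = mutable[int(rng.integers(len(mutable)))]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(3))]
    else:
        raise RuntimeError("failed to scrub accidental motifs")

    planted_rows = [
        {
            "replicon_id": replicon_id,
            "position": s + 1,  # 1-based G position
            "strand": "+",
            "motif_class": MOTIF_CLASS[m],
        }
        for s, m in sorted(motif_of.items())
    ]
    planted = pd.DataFrame(
        planted_rows,
        columns=["replicon_id", "position", "strand", "motif_class"],
    )
    site_frames = []
    for motif in MOTIFS:
        cls = MOTIF_CLASS[motif]
        sub = planted[planted["motif_class"] == cls]
        n_mod = int(round(modified_fraction * len(sub)))
        if n_mod:
            idx = rng.choice(len(sub), size=n_mod, replace=False)
            site_frames.append(sub.iloc[np.sort(idx)])
    sites = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else planted.iloc[0:0].copy()
    )
    return "".join(seq), sites, planted


# ---------------------------------------------------------------------------
# competition assays
# ---------------------------------------------------------------------------


def _trajectory(true_w: float, f0: float, n_transfers: int, dilution: float):
    """Deterministic strain-A fraction trajectory under fixed relative fitness.

    Per transfer, solves for the end-of-day fraction f' such that
    doublings(B) = true_w * doublings(A) while the whole culture expands by
    the dilution factor.
    """
    fracs = [f0]
    f = f0
    for _ in range(n_transfers):
        def gap(fp, f=f):
            return doublings(1 - f, 1 - fp, 1, dilution) - true_w * doublings(
                f, fp, 1, dilution
            )

        eps = 1e-9
        f = float(brentq(gap, eps, 1 - eps, xtol=1e-12))
        if not (1e-6 < f < 1 - 1e-6):
            raise ValueError(
                "trajectory approaches fixation within the horizon; shorten it"
            )
        fracs.append(f)
    return fracs


def simulate_competition(
    true_w: float,
    f0: float = 0.52,
    n_transfers: int = 5,
    dilution: float = 100.0,
    colonies_per_sample: int = 100,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Colony-count table from a serial-transfer competition.

    The deterministic fraction trajectory implied by ``true_w`` is sampled at
    every day with binomial colony picking (``colonies_per_sample`` per time
    point and replicate). Columns: time, replicate, strain_a_count, total.
    """
    if true_w <= 0:
        raise ValueError("true_w must be positive")
    if not (0 < f0 < 1):
        raise ValueError("f0 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    fracs = _trajectory(true_w, f0, n_transfers, dilution)
    rows = []
    for rep in range(1, replicates + 1):
        for t, f in enumerate(fracs):
            count = int(rng.binomial(colonies_per_sample, f))
            rows.append(
                {
                    "time": t,
                    "replicate": rep,
                    "strain_a_count": count,
                    "total": colonies_per_sample,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def simulate_de_table(
    n_genes: int,
    n_deg: int,
    seed: int,
    pt_prob: float = 0.33,
    pt_enrichment: float = 0.0,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE table with planted DEGs plus a per-gene PT-site count table.

    Planted DEGs satisfy ``fdr < fdr_max`` and ``|FC| > fc_min`` by
    construction; non-DEGs fail the FDR threshold. A gene carries >= 1 PT site
    with probability ``pt_prob`` (+ ``pt_enrichment`` for DEGs); site counts
    for carriers are 1 + Poisson(2).
    """
    if n_deg > n_genes:
        raise ValueError("n_deg must not exceed n_genes")
    rng = np.random.default_rng(seed)
    lfc_min = float(np.log2(fc_min))
    rows, pt_rows = [], []
    for i in range(n_genes):
        gene_id = f"gene{i:05d}"
        is_deg = i < n_deg
        if is_deg:
            lfc = float(rng.uniform(lfc_min + 0.2, 4.0)) * (
                1 if rng.random() < 0.5 else -1
            )
            fdr = float(rng.uniform(1e-6, fdr_max * 0.98))
        else:
            lfc = float(rng.normal(0, 0.5))
            fdr = float(rng.uniform(fdr_max * 1.2, 1.0))
        rows.append({"gene_id": gene_id, "log2fc": lfc, "fdr": fdr})
        p_site = min(1.0, pt_prob + (pt_enrichment if is_deg else 0.0))
        has_site = rng.random() < p_site
        n_sites = int(1 + rng.poisson(2)) if has_site else 0
        n_a = int(rng.binomial(n_sites, 0.5)) if n_sites else 0
        pt_rows.append(
            {
                "gene_id": gene_id,
                "n_gpsa": n_a,
                "n_gpst": n_sites - n_a,
                "n_pt_sites": n_sites,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(pt_rows)
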