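"""Majority-rules viral taxonomy for prophage regions and per-genome counts.

A prophage region (predicted externally, e.g. by VIBRANT) is assigned to a
viral family when at least half of its proteins cast their vote for that
family; a protein votes through its best hit with bitscore >= 50 against a
viral reference set, and abstains when it has no qualifying hit or when two
families tie for its best bitscore. The vote denominator is the full protein
complement of the region, so a region of mostly hypothetical proteins stays
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import GenomeRecord, HomologyHit, ProphageRegion, ValidationError

__all__ = ["FamilyAssignment", "assign_family", "prophage_abundance"]


@dataclass(frozen=True)
class FamilyAssignment:
    region: ProphageRegion
    family: str  # viral family or "unclassified"
    fraction_assigned: float
    n_proteins: int


def assign_family(
    region: ProphageRegion,
    hits: list[HomologyHit],
    bitscore_min: float = 50.0,
    majority: float = 0.5,
) -> FamilyAssignment:
    """Assign a viral family to one region by the majority rule.

    Exact ties between two families at/above the majority threshold (possible
    only at exactly 0.5) are never resolved arbitrarily: the region is left
    unclassified.
    """
    if not region.protein_ids:
        raise ValidationError(
            f"region {region.genome_id}:{region.replicon_id}:{region.start}-"
            f"{region.end} has no proteins; cannot assign taxonomy"
        )
    by_protein: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_id in region_protein_set(region):
            by_protein.setdefault(h.query_id, []).append(h)

    votes: dict[str, int] = {}
    for pid in region.protein_ids:
        qualifying = [h for h in by_protein.get(pid, []) if h.bitscore >= bitscore_min]
        if not qualifying:
            continue
        best_score = max(h.bitscore for h in qualifying)
        best_families = {h.subject_family for h in qualifying if h.bitscore == best_score}
        if len(best_families) != 1:
            continue  # ambiguous best hit: abstain
        fam = best_families.pop()
        votes[fam] = votes.get(fam, 0) + 1

    n = len(region.protein_ids)
    winners = [f for f, v in votes.items() if v / n >= majority]
    if len(winners) == 1:
        fam = winners[0]
        return FamilyAssignment(region, fam, votes[fam] / n, n)
    top = max(votes.values()) / n if votes else 0.0
    return FamilyAssignment(region, "unclassified", top, n)


def region_protein_set(region: ProphageRegion) -> set[str]:
    return set(region.protein_ids)


def prophage_abundance(
    genomes: list[GenomeRecord] | list[str],
    regions: list[ProphageRegion],
) -> pd.DataFrame:
    """Per-genome prophage count and binary occurrence.

    ``genomes`` may be records or bare genome ids; genomes absent from the
    region table get count 0.
    """
    ids = [g.genome_id if isinstance(g, GenomeRecord) else str(g) for g in genomes]
    counts = {i: 0 for i in ids}
    for r in regions:
        if r.genome_id in counts:
            counts[r.genome_id] += 1
    return pd.DataFrame(
        {
            "genome_id": ids,
            "n_prophages": [counts[i] for i in ids],
            "has_prophage": [counts[i] > 0 for i in ids],
        }
    )
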