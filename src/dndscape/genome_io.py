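"""Input/output for all external formats and the coordinate/ordinal conventions.

Every downstream rule in the package (cluster adjacency, the 30-ORF
restriction-modification linkage, PT-site-to-gene mapping) operates on the
in-memory types defined here:

* coordinates are stored 0-based half-open (``start < end``); GFF3 I/O converts
  from/to the 1-based inclusive convention of the format, and every position
  shown to a user is 1-based inclusive;
* each protein-coding gene carries an *ordinal*, its rank along its replicon
  when CDS features are sorted by start (ties broken by end, then gene id).
  Ordinals are the "ORF" unit of the adjacency and distance rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd

__all__ = [
    "GeneFeature",
    "Replicon",
    "GenomeRecord",
    "HomologyHit",
    "ProphageRegion",
    "ParseError",
    "SchemaError",
    "ValidationError",
    "assign_ordinals",
    "read_gff3",
    "write_gff3",
    "read_hits_tsv",
    "read_taxonomy_tsv",
    "read_prophage_tsv",
    "read_sites_tsv",
    "read_de_tsv",
    "read_competition_csv",
]

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class ParseError(ValueError):
    """A line or row of an input file could not be parsed."""


class SchemaError(ValueError):
    """An input table is missing a required column or carries no usable one."""


class ValidationError(ValueError):
    """A parsed record violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One CDS on a replicon; 0-based half-open coordinates internally."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    ordinal: int = -1
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.gene_id}: need 0 <= start < end, "
                f"got ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.gene_id}: strand must be +/-")

    def contains(self, pos0: int) -> bool:
        """Whether the 0-based position falls inside the feature."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    length: int
    circular: bool = False


@dataclass
class GenomeRecord:
    """An annotated genome: replicons, ordered CDS features, taxonomy labels."""

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {r.replicon_id: r.length for r in self.replicons}
        for f in self.features:
            if f.replicon_id not in lengths:
                raise ValidationError(
                    f"genome {self.genome_id}: feature {f.gene_id} on unknown "
                    f"replicon {f.replicon_id}"
                )
            if f.end > lengths[f.replicon_id]:
                raise ValidationError(
                    f"genome {self.genome_id}: feature {f.gene_id} extends past "
                    f"replicon {f.replicon_id} ({f.end} > {lengths[f.replicon_id]})"
                )

    @property
    def genus(self) -> str | None:
        return self.taxonomy.get("genus") or None

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def features_by_replicon(self, replicon_id: str) -> list[GeneFeature]:
        return sorted(
            (f for f in self.features if f.replicon_id == replicon_id),
            key=lambda f: f.ordinal,
        )

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)


@dataclass(frozen=True)
class HomologyHit:
    """One aligned protein pair from a BLAST/DIAMOND tabular hit."""

    query_id: str
    subject_id: str
    subject_family: str
    pident: float
    aln_length: int
    evalue: float
    bitscore: float
    qlen: int | None = None
    qcov: float = float("nan")

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bitscore < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value/bitscore"
            )
        if not (0 < self.qcov <= 1) and not math.isnan(self.qcov):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: qcov {self.qcov} "
                "outside (0, 1]"
            )


@dataclass
class ProphageRegion:
    """A prophage element called by an external predictor, with its proteins."""

    genome_id: str
    replicon_id: str
    start: int  # 0-based half-open, like GeneFeature
    end: int
    protein_ids: list[str] = field(default_factory=list)
    assigned_family: str = "unclassified"


# ---------------------------------------------------------------------------
# ordinals
# ---------------------------------------------------------------------------


def assign_ordinals(features: list[GeneFeature]) -> list[GeneFeature]:
    """Assign per-replicon ordinals 0..N-1 sorted by (start, end, gene_id).

    Only CDS features should be passed; ordinals are a permutation within each
    replicon by construction.
    """
    out: list[GeneFeature] = []
    by_rep: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_rep.setdefault(f.replicon_id, []).append(f)
    for rep_feats in by_rep.values():
        rep_feats.sort(key=lambda f: (f.start, f.end, f.gene_id))
        for i, f in enumerate(rep_feats):
            out.append(
                GeneFeature(
                    gene_id=f.gene_id,
                    replicon_id=f.replicon_id,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    ordinal=i,
                    product=f.product,
                )
            )
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prevalidate_gff3(path: str) -> None:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(">"):
                if line.startswith(">"):
                    return  # embedded FASTA section: stop validating
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}: malformed GFF3 line {lineno}")


def read_gff3(path: str, genome_id: str | None = None) -> GenomeRecord:
    """Read a GFF3 file into a :class:`GenomeRecord` with CDS ordinals assigned.

    Replicon lengths come from ``##sequence-region`` pragmas; a replicon is
    circular when a ``region`` feature carries ``Is_circular=true``. A file with
    zero CDS features yields a valid, empty-feature record.
    """
    _prevalidate_gff3(path)
    if genome_id is None:
        genome_id = path.rsplit("/", 1)[-1].removesuffix(".gff3").removesuffix(".gff")
    with open(path, encoding="utf-8") as fh:
        body_lines = [
            ln for ln in fh if ln.strip() and not ln.startswith(("#", ">"))
        ]
    if not body_lines:
        # zero features: still a valid (empty) record; replicons from pragmas
        warnings.warn(f"{path}: no features found", stacklevel=2)
        replicons = []
        with open(path, encoding="utf-8") as fh:
            for ln in fh:
                if ln.startswith("##sequence-region"):
                    parts = ln.split()
                    if len(parts) >= 4:
                        replicons.append(Replicon(parts[1], int(parts[3]), False))
        return GenomeRecord(genome_id=genome_id, replicons=replicons, features=[])
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    replicons: dict[str, Replicon] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                replicons[parts[1]] = Replicon(parts[1], int(parts[3]), False)
    circular_ids = set()
    for ftype in ("region", "chromosome", "plasmid"):
        try:
            for feat in db.features_of_type(ftype):
                val = feat.attributes.get("Is_circular", ["false"])[0]
                if val.lower() == "true":
                    circular_ids.add(feat.seqid)
                replicons.setdefault(feat.seqid, Replicon(feat.seqid, feat.end, False))
        except Exception:  # noqa: BLE001 - feature type absent
            continue

    features: list[GeneFeature] = []
    for feat in db.features_of_type("CDS"):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [feat.id])[0]
        product = (attrs.get("product") or [None])[0]
        features.append(
            GeneFeature(
                gene_id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                product=product,
            )
        )
    for f in features:
        if f.replicon_id not in replicons:
            replicons[f.replicon_id] = Replicon(f.replicon_id, f.end, False)
    replicon_list = [
        Replicon(r.replicon_id, r.length, r.replicon_id in circular_ids)
        for r in replicons.values()
    ]
    return GenomeRecord(
        genome_id=genome_id,
        replicons=replicon_list,
        features=assign_ordinals(features),
    )


def write_gff3(genome: GenomeRecord, path: str) -> None:
    """Write a record back to GFF3 (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
        for rep in genome.replicons:
            if rep.circular:
                fh.write(
                    f"{rep.replicon_id}\tdndscape\tregion\t1\t{rep.length}\t.\t+\t.\t"
                    f"ID=region-{rep.replicon_id};Is_circular=true\n"
                )
        for f in sorted(genome.features, key=lambda f: (f.replicon_id, f.ordinal)):
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon_id}\tdndscape\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tabular hits
# ---------------------------------------------------------------------------

_OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_tsv(path: str, family_map: dict[str, str]) -> list[HomologyHit]:
    """Parse BLAST/DIAMOND outfmt-6 TSV into :class:`HomologyHit` records.

    The standard 12 columns must be followed by ``qlen`` (13th) and optionally
    ``qcovhsp`` in percent (14th): query coverage is ``qcovhsp/100`` when given,
    else ``length/qlen``. Subjects absent from ``family_map`` keep family
    ``"unknown"``.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}: row {lineno}: expected >=12 columns")
            if len(cols) < 13:
                raise SchemaError(
                    f"{path}: row {lineno}: need qlen (col 13) or qcovhsp "
                    "(col 14) to derive query coverage"
                )
            try:
                pident = float(cols[2])
                aln_length = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
                qlen = int(cols[12])
                qcov = float(cols[13]) / 100.0 if len(cols) >= 14 else aln_length / qlen
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: non-numeric field ({exc})")
            subject = cols[1]
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=subject,
                    subject_family=family_map.get(subject, "unknown"),
                    pident=pident,
                    aln_length=aln_length,
                    evalue=evalue,
                    bitscore=bitscore,
                    qlen=qlen,
                    qcov=qcov,
                )
            )
    return hits


def read_family_map_tsv(path: str) -> dict[str, str]:
    """Two-column TSV mapping subject_id -> family."""
    df = _read_table(path, sep="\t", required=["subject_id", "family"])
    return dict(zip(df["subject_id"], df["family"]))


# ---------------------------------------------------------------------------
# headered tables
# ---------------------------------------------------------------------------


def _read_table(path: str, sep: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"genome_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_taxonomy_tsv(path: str) -> pd.DataFrame:
    """Genome taxonomy table: ``genome_id`` plus the six standard ranks.

    Rows with a missing genus are kept but flagged ineligible for the
    correlation stages (``eligible_for_correlation`` column).
    """
    df = _read_table(path, "\t", ["genome_id", "genus"])
    for rank in TAXONOMY_RANKS:
        if rank not in df.columns:
            df[rank] = pd.NA
    df["eligible_for_correlation"] = df["genus"].notna() & (
        df["genus"].astype(str).str.len() > 0
    )
    return df


def read_prophage_tsv(path: str) -> list[ProphageRegion]:
    """Prophage region table: genome_id, replicon_id, start, end (1-based
    inclusive), protein_ids (comma-separated)."""
    df = _read_table(path, "\t", ["genome_id", "replicon_id", "start", "end"])
    regions = []
    for row in df.itertuples(index=False):
        proteins = []
        if "protein_ids" in df.columns and isinstance(row.protein_ids, str):
            proteins = [p for p in row.protein_ids.split(",") if p]
        regions.append(
            ProphageRegion(
                genome_id=str(row.genome_id),
                replicon_id=str(row.replicon_id),
                start=int(row.start) - 1,
                end=int(row.end),
                protein_ids=proteins,
            )
        )
    return regions


def read_sites_tsv(path: str) -> pd.DataFrame:
    """PT-site table: replicon_id, position (1-based G), strand, motif_class."""
    df = _read_table(path, "\t", ["replicon_id", "position", "strand", "motif_class"])
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(
            f"{path}: strand must be + or - (offending rows: "
            f"{df.index[bad].tolist()[:5]})"
        )
    bad_cls = ~df["motif_class"].isin(["GpsAAC", "GpsTTC"])
    if bad_cls.any():
        raise ValidationError(f"{path}: motif_class must be GpsAAC or GpsTTC")
    return df


def read_de_tsv(path: str) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2fc, fdr."""
    df = _read_table(path, "\t", ["gene_id", "log2fc", "fdr"])
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValidationError(f"{path}: fdr outside [0, 1]")
    return df


def read_competition_csv(path: str) -> pd.DataFrame:
    """Competition colony counts: time, replicate, strain_a_count, total."""
    df = _read_table(path, ",", ["time", "replicate", "strain_a_count", "total"])
    if (df["total"] <= 0).any():
        raise ValidationError(f"{path}: colony total must be positive at every "
                              "time point")
    if ((df["strain_a_count"] < 0) | (df["strain_a_count"] > df["total"])).any():
        raise ValidationError(f"{path}: strain_a_count outside [0, total]")
    return df
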