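"""Readers and writers for the external file formats.

The pipeline consumes four kinds of input:

* protein isoform sequences in FASTA,
* a group manifest (TSV: ``group_id  isoform_id  gene_id  species``)
  assigning each isoform to a gene, a species and a one-to-one
  orthologue group,
* functional-signature assignments in InterProScan's tab-separated
  output dialect, and
* intrinsic-disorder annotations, either as per-protein residue
  intervals or as dense per-residue score tracks.

Clustering results are written back out as a flat TSV, one row per
isoform, mirroring the usual "cluster membership table" layout.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The residue symbols accepted in input proteins: the 20 standard amino
#: acids plus the ambiguity codes B/Z/X and selenocysteine U.  Stop
#: characters ('*') and whitespace are rejected outright.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXU")

GAP = "-"


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformRecord:
    """One protein isoform: the product of a particular splicing of a gene."""

    isoform_id: str
    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"isoform {self.isoform_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"isoform {self.isoform_id!r}: invalid residue symbol(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologueGroup:
    """A one-to-one orthologue group: one gene per species, two species,
    with all the protein isoforms of both genes."""

    group_id: str
    species_a: str
    species_b: str
    isoforms: list[IsoformRecord]

    def __post_init__(self) -> None:
        ids = [iso.isoform_id for iso in self.isoforms]
        if len(ids) != len(set(ids)):
            raise FormatError(f"group {self.group_id!r}: duplicate isoform ids")
        species = {iso.species for iso in self.isoforms}
        if species != {self.species_a, self.species_b} or self.species_a == self.species_b:
            raise FormatError(
                f"group {self.group_id!r}: expected isoforms from exactly the "
                f"two species {self.species_a!r} and {self.species_b!r}, got {sorted(species)!r}"
            )
        for sp in (self.species_a, self.species_b):
            genes = {iso.gene_id for iso in self.isoforms if iso.species == sp}
            if len(genes) != 1:
                raise FormatError(
                    f"group {self.group_id!r}: species {sp!r} has genes "
                    f"{sorted(genes)!r}; one-to-one groups need exactly one"
                )

    @property
    def isoform_ids(self) -> list[str]:
        return [iso.isoform_id for iso in self.isoforms]

    def species_of(self, isoform_id: str) -> str:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso.species
        raise KeyError(isoform_id)

    def sequence_of(self, isoform_id: str) -> str:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso.sequence
        raise KeyError(isoform_id)

    def members_of(self, species: str) -> list[IsoformRecord]:
        return [iso for iso in self.isoforms if iso.species == species]


@dataclass(frozen=True)
class SignatureAssignment:
    """A (protein isoform, functional signature accession) match."""

    isoform_id: str
    signature_accession: str


@dataclass
class DisorderAnnotation:
    """Raw disorder annotation for one isoform: either residue intervals
    (1-based inclusive) or a dense per-residue score track."""

    isoform_id: str
    regions: list[tuple[int, int]] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        for start, end in self.regions:
            if start < 1 or start > end:
                raise FormatError(
                    f"isoform {self.isoform_id!r}: bad interval ({start}, {end})"
                )
        self.regions.sort()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a protein FASTA file as an ordered list of ``(id, sequence)``.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased.  Duplicate ids are an error.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    # Bio.SeqIO silently skips text before the first '>': catch that case.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">") and not records:
                raise FormatError(f"{path}:{lineno}: sequence data before any header")
            break
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with wrapped lines."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("group_id", "isoform_id", "gene_id", "species")


def read_manifest(path) -> list[dict]:
    """Read the group manifest TSV into per-row dicts (order preserved).

    Required header columns: group_id, isoform_id, gene_id, species.
    """
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return rows
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
        for row in reader:
            rows.append({col: row[col].strip() for col in MANIFEST_COLUMNS})
    return rows


def assemble_groups(
    manifest_rows: Sequence[dict],
    sequences: dict[str, str],
    strict: bool = False,
) -> list[OrthologueGroup]:
    """Join manifest rows with sequences into validated orthologue groups.

    Groups violating the one-to-one / two-species invariants are skipped
    with a logged warning (or raised when ``strict``).  An isoform listed
    in the manifest but absent from the FASTA is always fatal.
    """
    missing = sorted(
        {r["isoform_id"] for r in manifest_rows} - set(sequences)
    )
    if missing:
        raise FormatError(
            f"manifest isoforms absent from FASTA: {', '.join(missing)}"
        )

    by_group: dict[str, list[dict]] = {}
    for row in manifest_rows:
        by_group.setdefault(row["group_id"], []).append(row)

    groups: list[OrthologueGroup] = []
    for group_id, rows in by_group.items():
        species = sorted({r["species"] for r in rows})
        try:
            if len(species) != 2:
                raise FormatError(
                    f"group {group_id!r}: expected 2 species, found {species!r}"
                )
            isoforms = [
                IsoformRecord(
                    isoform_id=r["isoform_id"],
                    gene_id=r["gene_id"],
                    species=r["species"],
                    sequence=sequences[r["isoform_id"]],
                )
                for r in rows
            ]
            groups.append(
                OrthologueGroup(
                    group_id=group_id,
                    species_a=species[0],
                    species_b=species[1],
                    isoforms=isoforms,
                )
            )
        except FormatError as exc:
            if strict:
                raise
            logger.warning("skipping invalid group: %s", exc)
    return groups


def load_groups(fasta_path, manifest_path, strict: bool = False) -> list[OrthologueGroup]:
    """Convenience: read FASTA + manifest and assemble orthologue groups."""
    sequences = dict(read_fasta(fasta_path))
    return assemble_groups(read_manifest(manifest_path), sequences, strict=strict)


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------

def read_interproscan_tsv(path, signature_column: int = 5) -> list[SignatureAssignment]:
    """Read protein→signature assignments from an InterProScan-style TSV.

    Column 1 holds the protein accession and ``signature_column``
    (1-based, default 5 — the member-database signature accession of the
    standard InterProScan output) holds the signature.  Duplicate
    (protein, signature) pairs are collapsed; comment lines and rows too
    short to hold the signature column are skipped with a warning.
    """
    seen: set[tuple[str, str]] = set()
    out: list[SignatureAssignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < signature_column:
                logger.warning("%s:%d: short row skipped", path, lineno)
                continue
            iso, sig = fields[0].strip(), fields[signature_column - 1].strip()
            if not iso or not sig:
                logger.warning("%s:%d: empty accession, row skipped", path, lineno)
                continue
            if (iso, sig) in seen:
                continue
            seen.add((iso, sig))
            out.append(SignatureAssignment(iso, sig))
    return out


# ---------------------------------------------------------------------------
# Disorder TSV
# ---------------------------------------------------------------------------

def read_disorder_tsv(path, kind: str = "intervals") -> list[DisorderAnnotation]:
    """Read disorder annotations.

    ``kind='intervals'``: columns isoform_id, start, end (1-based
    inclusive); intervals are sorted per isoform.  ``kind='scores'``:
    columns isoform_id, position, score; the track must cover positions
    1..L contiguously.
    """
    if kind not in ("intervals", "scores"):
        raise ValueError(f"kind must be 'intervals' or 'scores', got {kind!r}")
    per_iso: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "isoform_id":  # optional header
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            iso = fields[0].strip()
            if iso not in per_iso:
                per_iso[iso] = []
                order.append(iso)
            if kind == "intervals":
                start, end = int(fields[1]), int(fields[2])
                if start > end:
                    raise FormatError(
                        f"{path}:{lineno}: interval start {start} > end {end}"
                    )
                per_iso[iso].append((start, end))
            else:
                per_iso[iso].append((int(fields[1]), float(fields[2])))

    out: list[DisorderAnnotation] = []
    for iso in order:
        if kind == "intervals":
            out.append(DisorderAnnotation(iso, regions=sorted(per_iso[iso])))
        else:
            entries = sorted(per_iso[iso])
            positions = [p for p, _ in entries]
            if positions != list(range(1, len(positions) + 1)):
                raise FormatError(
                    f"{path}: score track for {iso!r} is not contiguous from 1"
                )
            out.append(
                DisorderAnnotation(iso, scores=[s for _, s in entries])
            )
    return out


# ---------------------------------------------------------------------------
# Cluster output TSV
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = (
    "group_id",
    "cluster_index",
    "isoform_id",
    "species",
    "is_anchor",
    "anchor_score",
)


def write_clusters_tsv(clusterings, path) -> None:
    """Write per-group sub-cluster assignments as a TSV.

    ``clusterings`` is an iterable of GroupClustering objects.  Rows are
    ordered by (group_id, cluster_index, species, isoform_id) so output
    is byte-identical across runs.
    """
    rows = []
    for gc in clusterings:
        for cl in gc.clusters:
            anchors = {cl.anchor_a, cl.anchor_b} if cl.anchor_a is not None else set()
            for member_id, species in cl.members:
                rows.append(
                    (
                        gc.group_id,
                        cl.cluster_index,
                        member_id,
                        species,
                        "true" if member_id in anchors else "false",
                        f"{cl.anchor_score:.6f}" if cl.anchor_score is not None else "",
                    )
                )
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[2]))
    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTER_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_clusters_tsv(path) -> list:
    """Read a clusters TSV back into GroupClustering objects.

    Used by the verification subcommands, which consume clustering
    output rather than recomputing it.
    """
    from .cluster import GroupClustering, SubCluster

    per_group: dict[str, dict[int, dict]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(CLUSTER_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: clusters TSV missing column(s) {sorted(missing)}")
        for row in reader:
            g = per_group.setdefault(row["group_id"], {})
            idx = int(row["cluster_index"])
            cl = g.setdefault(idx, {"members": [], "anchors": [], "score": None})
            cl["members"].append((row["isoform_id"], row["species"]))
            if row["is_anchor"] == "true":
                cl["anchors"].append(row["isoform_id"])
            if row["anchor_score"]:
                cl["score"] = float(row["anchor_score"])

    out = []
    for group_id in sorted(per_group):
        clusters = []
        for idx in sorted(per_group[group_id]):
            cl = per_group[group_id][idx]
            anchors = sorted(cl["anchors"])
            clusters.append(
                SubCluster(
                    cluster_index=idx,
                    anchor_a=anchors[0] if anchors else None,
                    anchor_b=anchors[1] if len(anchors) > 1 else None,
                    anchor_score=cl["score"],
                    members=sorted(cl["members"]),
                )
            )
        out.append(GroupClustering(group_id=group_id, clusters=clusters))
    return out
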