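"""Reference database construction: the Lac_groEL_database analogue.

Full-length groEL references are trimmed in silico to the primer-bounded
amplicon region and tied to species (or subspecies) labels from a
taxonomy table. Records that yield no product, or more than one, are kept
but flagged and excluded from classification targets.

Serialization is plain text: full-length FASTA + amplicon FASTA + a
taxonomy TSV (accession, species label, status, amplicon coordinates) + a
JSON metadata sidecar recording the primer pair and build parameters, so
the database round-trips field-for-field and interoperates with standard
classifiers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import ispcr
from .primers import LAC_GROEL, PrimerPair, normalize

__all__ = [
    "RefRecord",
    "ReferenceDB",
    "build_db",
    "build_db_from_records",
    "write_db",
    "read_db",
]

STATUS_OK = "ok"
STATUS_NO_PRODUCT = "no_product"
STATUS_MULTI_PRODUCT = "multi_product"


@dataclass
class RefRecord:
    accession: str
    species_label: str
    full_seq: str
    amplicon_seq: str | None = None
    amplicon_start: int | None = None  # 0-based, on full_seq
    amplicon_end: int | None = None
    amplify_status: str = STATUS_NO_PRODUCT

    def __post_init__(self) -> None:
        if not self.species_label:
            raise ValueError(f"{self.accession}: species label must be non-empty")
        if (self.amplicon_seq is not None) != (self.amplify_status == STATUS_OK):
            raise ValueError(
                f"{self.accession}: amplicon present iff status is '{STATUS_OK}'"
            )


@dataclass
class ReferenceDB:
    """Accession → (species label, full sequence, trimmed amplicon) records."""

    records: list[RefRecord] = field(default_factory=list)
    primer_pair: PrimerPair = LAC_GROEL
    version: str = "1"

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions: {', '.join(dupes)}")

    def ok_records(self) -> list[RefRecord]:
        """Records usable as classification targets."""
        return [r for r in self.records if r.amplify_status == STATUS_OK]

    def insert_seq(self, record: RefRecord) -> str:
        """Amplicon with the primer-covered windows removed.

        Classification identity is computed on these inserts because the
        primer-region bases are constrained by the primers themselves and
        would inflate identity.
        """
        if record.amplicon_seq is None:
            raise ValueError(f"{record.accession} has no amplicon")
        f, r = len(self.primer_pair.forward), len(self.primer_pair.reverse)
        return record.amplicon_seq[f:-r]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDB):
            return NotImplemented
        return (
            self.records == other.records
            and self.primer_pair == other.primer_pair
            and self.version == other.version
        )


def _read_taxonomy(path) -> dict[str, str]:
    """Two-column TSV: accession <tab> species label. '#' lines are comments."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed taxonomy line: {line!r}")
            if parts[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate accession {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def build_db(
    fasta_path,
    taxonomy_path,
    pair: PrimerPair = LAC_GROEL,
    min_len: int = ispcr.DEFAULT_MIN_LEN,
    max_len: int = ispcr.DEFAULT_MAX_LEN,
    version: str = "1",
) -> ReferenceDB:
    """Build a reference database from full-length references + taxonomy.

    Every FASTA id must appear in the taxonomy table. Each reference is
    trimmed to its in-silico product; references with 0 or >1 products are
    flagged ``no_product`` / ``multi_product``. The build is deterministic
    (FASTA order, fixed primer matching).
    """
    taxonomy = _read_taxonomy(taxonomy_path)
    records: list[RefRecord] = []
    seen: set[str] = set()
    missing: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate accession in FASTA: {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in taxonomy:
            missing.append(rec.id)
            continue
        full = normalize(str(rec.seq))
        amps = ispcr.amplify(full, pair, min_len, max_len, template_id=rec.id)
        if len(amps) == 1:
            a = amps[0]
            records.append(
                RefRecord(rec.id, taxonomy[rec.id], full, a.sequence,
                          a.start, a.end, STATUS_OK)
            )
        else:
            status = STATUS_NO_PRODUCT if not amps else STATUS_MULTI_PRODUCT
            records.append(RefRecord(rec.id, taxonomy[rec.id], full,
                                     amplify_status=status))
    if missing:
        raise ValueError(
            "FASTA ids missing from taxonomy table: " + ", ".join(missing)
        )
    return ReferenceDB(records=records, primer_pair=pair, version=version)


def build_db_from_records(
    templates: dict[str, str],
    taxonomy: dict[str, str],
    pair: PrimerPair = LAC_GROEL,
    min_len: int = ispcr.DEFAULT_MIN_LEN,
    max_len: int = ispcr.DEFAULT_MAX_LEN,
    version: str = "1",
) -> ReferenceDB:
    """Build a database from in-memory sequences (same rules as build_db)."""
    missing = [acc for acc in templates if acc not in taxonomy]
    if missing:
        raise ValueError(
            "sequence ids missing from taxonomy: " + ", ".join(missing)
        )
    records: list[RefRecord] = []
    for acc, seq in templates.items():
        full = normalize(seq)
        amps = ispcr.amplify(full, pair, min_len, max_len, template_id=acc)
        if len(amps) == 1:
            a = amps[0]
            records.append(RefRecord(acc, taxonomy[acc], full, a.sequence,
                                     a.start, a.end, STATUS_OK))
        else:
            status = STATUS_NO_PRODUCT if not amps else STATUS_MULTI_PRODUCT
            records.append(RefRecord(acc, taxonomy[acc], full,
                                     amplify_status=status))
    return ReferenceDB(records=records, primer_pair=pair, version=version)


def write_db(db: ReferenceDB, outdir) -> None:
    """Serialize a database to a directory of plain-text files."""
    os.makedirs(outdir, exist_ok=True)
    full = [SeqRecord(Seq(r.full_seq), id=r.accession, description="")
            for r in db.records]
    SeqIO.write(full, os.path.join(outdir, "references.fasta"), "fasta")
    amps = [SeqRecord(Seq(r.amplicon_seq), id=r.accession, description="")
            for r in db.records if r.amplify_status == STATUS_OK]
    SeqIO.write(amps, os.path.join(outdir, "amplicons.fasta"), "fasta")
    with open(os.path.join(outdir, "taxonomy.tsv"), "w") as fh:
        fh.write("#accession\tspecies_label\tstatus\tamplicon_start\tamplicon_end\n")
        for r in db.records:
            s = "" if r.amplicon_start is None else str(r.amplicon_start)
            e = "" if r.amplicon_end is None else str(r.amplicon_end)
            fh.write(f"{r.accession}\t{r.species_label}\t{r.amplify_status}\t{s}\t{e}\n")
    meta = {
        "version": db.version,
        "primer_pair": {
            "name": db.primer_pair.name,
            "forward": db.primer_pair.forward,
            "reverse": db.primer_pair.reverse,
            "max_mismatches": db.primer_pair.max_mismatches,
            "clamp_len": db.primer_pair.clamp_len,
        },
    }
    with open(os.path.join(outdir, "db.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_db(indir) -> ReferenceDB:
    """Load a database written by :func:`write_db` (round-trip identity)."""
    with open(os.path.join(indir, "db.json")) as fh:
        meta = json.load(fh)
    pair = PrimerPair(**meta["primer_pair"])
    full = {r.id: str(r.seq) for r in
            SeqIO.parse(os.path.join(indir, "references.fasta"), "fasta")}
    records: list[RefRecord] = []
    path = os.path.join(indir, "taxonomy.tsv")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: malformed taxonomy line: {line!r}")
            acc, label, status, s, e = parts
            if acc not in full:
                raise ValueError(f"{path}:{lineno}: {acc!r} not in references.fasta")
            seq = full[acc]
            if status == STATUS_OK:
                start, end = int(s), int(e)
                records.append(RefRecord(acc, label, seq, seq[start:end],
                                         start, end, STATUS_OK))
            else:
                records.append(RefRecord(acc, label, seq, amplify_status=status))
    return ReferenceDB(records=records, primer_pair=pair, version=meta["version"])
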