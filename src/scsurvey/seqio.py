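"""Protein sequence IO and the query-panel manifest.

Sequences are plain strings over the 20 amino-acid letters plus X
(unknown residue, present in many database records).  Other ambiguity
codes (B, Z, U, J, O) and the stop symbol ``*`` are rejected at parse
time so that downstream scoring semantics stay unambiguous.

The query panel is the fixed set of 33 synaptonemal-complex proteins
from eight model organisms (yeasts, *Arabidopsis*, nematode, fly,
zebrafish, sablefish, mouse) that the survey uses as queries.  The
manifest ships with the package as a small TSV; resolving accessions to
sequences is a separate, optional, network-dependent step so everything
else works offline.
"""

from __future__ import annotations

import urllib.request
import urllib.error
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AMINO_ACIDS + "X"
_VALID = frozenset(ALPHABET)

#: organism tags admitted in the panel manifest
ORGANISM_TAGS = frozenset({"At", "Dm", "Mm", "Ce", "Sc", "Sp", "Dr", "Af"})

PANEL_SIZE = 33


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass
class ProteinRecord:
    """One protein sequence with its accession, description and taxon tag."""

    id: str
    seq: str
    description: str = ""
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)}; "
                f"allowed are the 20 amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CompositionVector:
    """Residue frequencies of one sequence (fractions sum to 1)."""

    freq: dict[str, float]
    length: int


def composition(record: ProteinRecord) -> CompositionVector:
    """Residue composition of ``record``; absent residues get frequency 0."""
    n = len(record.seq)
    freq = {a: 0.0 for a in ALPHABET}
    for a in record.seq:
        freq[a] += 1.0
    for a in freq:
        freq[a] /= n
    return CompositionVector(freq=freq, length=n)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein multi-FASTA file.

    The header token before the first whitespace becomes the record id;
    the remainder of the header line becomes the description.  Raises
    :class:`FastaParseError` naming the line number on a malformed
    header or an illegal residue.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(lineno: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: record {header!r} (line {header_line}) has no sequence"
            )
        try:
            records.append(ProteinRecord(id=header, seq=seq, description=desc))
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: line {header_line}: {exc}"
            ) from exc

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                body = line[1:].strip()
                if not body:
                    raise FastaParseError(f"{path}: line {lineno}: empty FASTA header")
                parts = body.split(None, 1)
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                token = line.upper()
                bad = set(token) - _VALID
                if bad:
                    raise FastaParseError(
                        f"{path}: line {lineno}: illegal residue(s) {sorted(bad)}"
                    )
                chunks.append(token)
        flush(lineno=-1)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (``width`` residues per line)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Query panel (the 33-protein manifest)
# ---------------------------------------------------------------------------

@dataclass
class PanelEntry:
    name: str        # protein name, e.g. "SYCP1"
    organism: str    # model-organism tag, e.g. "Mm"
    database: str    # "RefSeq" | "GenBank" | "Swiss-Prot"
    accession: str   # bare database id, e.g. "NP_035646.2"


@dataclass
class QueryPanel:
    """The fixed query set: 33 SC proteins of the model organisms."""

    entries: list[PanelEntry]
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in panel: {dupes}")
        bad = sorted({e.organism for e in self.entries} - ORGANISM_TAGS)
        if bad:
            raise ValueError(f"unknown organism tag(s): {bad}")

    def resolved(self) -> bool:
        return all(e.accession in self.records for e in self.entries)

    def missing(self) -> list[str]:
        return [e.accession for e in self.entries if e.accession not in self.records]

    def attach_records(self, records: Iterable[ProteinRecord]) -> None:
        """Attach sequences (matched by accession) to panel entries."""
        by_id = {r.id: r for r in records}
        for e in self.entries:
            if e.accession in by_id:
                self.records[e.accession] = by_id[e.accession]

    def query_records(self) -> list[ProteinRecord]:
        miss = self.missing()
        if miss:
            raise ValueError(f"panel has unresolved accessions: {miss}")
        return [self.records[e.accession] for e in self.entries]


def load_panel(path: str | Path | None = None, expected_size: int = PANEL_SIZE) -> QueryPanel:
    """Load the panel manifest (TSV: name, organism, database, accession).

    With no ``path`` the packaged manifest of the 33 query proteins is
    used.  Manifests whose entry count differs from ``expected_size`` or
    with duplicate accessions are rejected.
    """
    if path is None:
        src = resources.files("scsurvey.data").joinpath("query_panel.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    entries: list[PanelEntry] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"panel manifest line {lineno}: expected 4 tab-separated fields")
        entries.append(PanelEntry(*[p.strip() for p in parts]))
    if expected_size is not None and len(entries) != expected_size:
        raise ValueError(
            f"panel manifest has {len(entries)} entries; expected {expected_size}"
        )
    return QueryPanel(entries=entries)


# ---------------------------------------------------------------------------
# Optional network fetch (NCBI / UniProt); everything else works offline
# ---------------------------------------------------------------------------

_NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={acc}&rettype=fasta&retmode=text"
)
_UNIPROT = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def _fetch_one(entry: PanelEntry, timeout: float) -> ProteinRecord:
    url = (_UNIPROT if entry.database == "Swiss-Prot" else _NCBI_EFETCH).format(
        acc=entry.accession
    )
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise RuntimeError(f"unexpected response for {entry.accession}")
    seq = "".join(lines[1:])
    return ProteinRecord(
        id=entry.accession,
        seq=seq,
        description=f"{entry.name} {entry.organism}",
        taxon=entry.organism,
    )


def fetch_panel_records(
    panel: QueryPanel,
    cache_path: str | Path | None = None,
    accessions: Iterable[str] | None = None,
    timeout: float = 15.0,
) -> list[ProteinRecord]:
    """Fetch panel sequences from NCBI/UniProt and attach them to the panel.

    Network-dependent; the result is optionally written to ``cache_path``
    (FASTA) so later runs can use :func:`read_fasta` +
    :meth:`QueryPanel.attach_records` instead.  Raises ``OSError`` when
    the databases are unreachable.
    """
    wanted = set(accessions) if accessions is not None else None
    fetched: list[ProteinRecord] = []
    for entry in panel.entries:
        if wanted is not None and entry.accession not in wanted:
            continue
        try:
            fetched.append(_fetch_one(entry, timeout))
        except (urllib.error.URLError, TimeoutError) as exc:
            raise OSError(
                f"could not fetch {entry.accession} from sequence databases "
                f"(network unavailable?): {exc}"
            ) from exc
    panel.attach_records(fetched)
    if cache_path is not None:
        write_fasta(fetched, cache_path)
    return fetched
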