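"""I/O for the standard formats the pipeline touches.

Readers and writers for transcript FASTA (GENCODE-style pipe-delimited
headers or plain headers with an optional biotype sidecar), canonical
proteome FASTA, cryptoprotein-database FASTA with structured headers,
PSM (peptide-spectrum match) tables, and cohort design tables.

PSM tables are the ingestion boundary of the package: spectra are searched
by external engines and we consume their tabular exports, so there is no
mzML/mzIdentML parsing here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .orf_enumerator import CryptoDbEntry

logger = logging.getLogger(__name__)

#: Controlled vocabulary of transcript biotypes. Unknown labels are mapped
#: to ``other`` with a warning rather than raising, because annotation
#: releases drift in their label sets.
BIOTYPE_VOCABULARY = frozenset(
    {
        "protein_coding",
        "retained_intron",
        "processed_transcript",
        "antisense",
        "nonsense_mediated_decay",
        "lincRNA",
        "processed_pseudogene",
        "TEC",
        "sense_intronic",
        "macro_lncRNA",
        "misc_RNA",
        "pseudogene",
        "sense_overlapping",
        "transcribed_processed_pseudogene",
        "transcribed_unprocessed_pseudogene",
        "other",
    }
)

_VALID_NT = frozenset("ACGTN")
_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ConfigError(ValueError):
    """A column map or parameter set is inconsistent with the input."""


def normalize_biotype(label: str) -> str:
    """Map a raw biotype label onto the controlled vocabulary.

    Unknown labels become ``other`` (with a logged warning); this never
    raises.
    """
    label = label.strip()
    if label in BIOTYPE_VOCABULARY:
        return label
    logger.warning("unknown biotype %r mapped to 'other'", label)
    return "other"


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript: the unit of in-silico translation.

    ``sequence`` is the sense strand, uppercase over {A,C,G,T,N}.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if self.biotype not in BIOTYPE_VOCABULARY:
            raise ValueError(f"{self.transcript_id}: biotype {self.biotype!r} not in vocabulary")


@dataclass
class PsmRecord:
    """One peptide-spectrum match from an upstream search engine.

    ``q_value`` is the peptide-level FDR estimate in [0, 1]; ``assignment``
    is filled by the two-pass assignment stage and starts ``unassigned``.
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    q_value: float
    score: float
    assignment: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.peptide or not set(self.peptide) <= _VALID_AA:
            raise ValueError(f"invalid peptide {self.peptide!r}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        if self.assignment not in ("canonical", "crypto", "unassigned"):
            raise ValueError(f"invalid assignment {self.assignment!r}")


@dataclass(frozen=True)
class CohortDesign:
    """One sample (pool) of a case/control design.

    ``pool_size`` is the number of pooled individuals; ``stratum_id`` is the
    matching stratum (required for conditional-logistic analysis); ``cohort``
    names the experiment the sample belongs to (e.g. ``newly_diagnosed`` or
    ``pre_diagnostic``).
    """

    sample_id: str
    group: str
    pool_size: int
    stratum_id: str | None = None
    cohort: str = "newly_diagnosed"

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be case/control, got {self.group!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be a positive integer")


def validate_design(design: Sequence[CohortDesign], sample_ids: Iterable[str] | None = None) -> None:
    """Check design-table invariants.

    Every sample id must be unique; if ``sample_ids`` (e.g. from a PSM table)
    is given, each must appear exactly once in the design. Strata, when
    present, must contain at least one case and one control.
    """
    seen: dict[str, CohortDesign] = {}
    for d in design:
        if d.sample_id in seen:
            raise FormatError(f"duplicate sample_id {d.sample_id!r} in design")
        seen[d.sample_id] = d
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(seen))
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
    strata: dict[str, set[str]] = {}
    for d in design:
        if d.stratum_id is not None:
            strata.setdefault(d.stratum_id, set()).add(d.group)
    bad = sorted(s for s, groups in strata.items() if groups != {"case", "control"})
    if bad:
        raise FormatError(f"strata without both a case and a control: {bad}")


# ---------------------------------------------------------------------------
# transcript FASTA

# GENCODE pipe-delimited header: field 0 transcript_id, 1 gene_id,
# 5 gene_name, 7 biotype. Positions are configurable because layouts
# drift across releases.
GENCODE_FIELDS = {"transcript_id": 0, "gene_id": 1, "gene_name": 5, "biotype": 7}


def read_transcript_fasta(
    path: str | Path,
    header_dialect: str = "gencode",
    biotype_sidecar: str | Path | None = None,
    field_positions: Mapping[str, int] | None = None,
) -> list[TranscriptRecord]:
    """Read a transcript FASTA into :class:`TranscriptRecord` objects.

    ``gencode`` dialect splits the header on ``|``; ``plain`` takes the first
    whitespace token as transcript_id with biotype ``other`` unless a
    two-column sidecar TSV (transcript_id, biotype) supplies it. Sequences
    are uppercased with U normalized to T; records with characters outside
    {A,C,G,T,N} are rejected per record with a warning, never fatally.
    """
    if header_dialect not in ("gencode", "plain"):
        raise ConfigError(f"unknown header dialect {header_dialect!r}")
    positions = dict(GENCODE_FIELDS if field_positions is None else field_positions)
    sidecar: dict[str, str] = {}
    if biotype_sidecar is not None:
        sc = pd.read_csv(biotype_sidecar, sep="\t", header=None, names=["transcript_id", "biotype"], dtype=str)
        sidecar = dict(zip(sc["transcript_id"], sc["biotype"]))

    records: list[TranscriptRecord] = []
    seen_ids: set[str] = set()
    n_entries = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending content
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    for rec in parsed:
        n_entries += 1
        header = rec.description
        if header_dialect == "gencode":
            fields = header.split("|")
            if len(fields) < 8:
                logger.warning("gencode header with <8 fields (%r): biotype set to 'other'", header)
                tid = fields[positions["transcript_id"]] if fields else rec.id
                gid, gname, biotype = "", "", "other"
            else:
                tid = fields[positions["transcript_id"]].strip()
                gid = fields[positions["gene_id"]].strip()
                gname = fields[positions["gene_name"]].strip()
                biotype = normalize_biotype(fields[positions["biotype"]])
        else:
            tid = rec.id
            gid, gname = "", ""
            biotype = normalize_biotype(sidecar[tid]) if tid in sidecar else "other"
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            logger.warning("transcript %s rejected: empty sequence", tid)
            continue
        if not set(seq) <= _VALID_NT:
            bad = sorted(set(seq) - _VALID_NT)
            logger.warning("transcript %s rejected: invalid characters %s", tid, bad)
            continue
        if tid in seen_ids:
            logger.warning("duplicate transcript_id %s rejected", tid)
            continue
        seen_ids.add(tid)
        records.append(TranscriptRecord(tid, gid, gname, biotype, seq))
    if n_entries == 0:
        logger.warning("no FASTA entries in %s", path)
    return records


def read_proteome_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a canonical proteome FASTA as ``(accession, sequence)`` pairs.

    Sequences are uppercased; trailing stop symbols (``*``) are stripped.
    """
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if seq:
            out.append((rec.id, seq))
    return out


# ---------------------------------------------------------------------------
# cryptoDB FASTA

_CRYPTODB_HEADER = re.compile(
    r"^(?P<orf_id>[^|]+)\|(?P<tids>[^|]+)\|(?P<biotypes>[^|]+)\|f(?P<frame>\d)\|"
    r"(?P<nt_start>\d+)\|(?P<nt_end>\d+)\|(?P<codon_count>\d+)$"
)


def write_cryptodb_fasta(entries: Sequence["CryptoDbEntry"], path: str | Path) -> None:
    """Write cryptoDB entries to FASTA with a structured pipe-delimited header.

    Header layout: ``orf_id|tid1,tid2,...|bt1,bt2,...|f<frame>|nt_start|nt_end|codon_count``
    where the transcript-id and biotype lists carry the full provenance in
    parallel order (first pair is the representative source). Round-trips
    losslessly through :func:`read_cryptodb_fasta`.
    """
    path = Path(path)
    try:
        with path.open("w") as fh:
            for e in entries:
                tids = ",".join(t for t, _ in e.provenance)
                bts = ",".join(b for _, b in e.provenance)
                fh.write(
                    f">{e.orf_id}|{tids}|{bts}|f{e.frame}|{e.nt_start}|{e.nt_end}|{e.codon_count}\n"
                )
                for i in range(0, len(e.aa_sequence), 60):
                    fh.write(e.aa_sequence[i : i + 60] + "\n")
    except OSError as exc:
        raise OSError(f"failed to write cryptoDB FASTA to {path}: {exc}") from exc


def read_cryptodb_fasta(path: str | Path) -> list["CryptoDbEntry"]:
    """Read a cryptoDB FASTA written by :func:`write_cryptodb_fasta`."""
    from .orf_enumerator import CryptoDbEntry  # local import breaks the cycle

    entries: list[CryptoDbEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CRYPTODB_HEADER.match(rec.description)
        if m is None:
            raise FormatError(f"unparseable cryptoDB header: {rec.description!r}")
        tids = m["tids"].split(",")
        bts = m["biotypes"].split(",")
        if len(tids) != len(bts):
            raise FormatError(f"provenance length mismatch in header: {rec.description!r}")
        entries.append(
            CryptoDbEntry(
                orf_id=m["orf_id"],
                transcript_id=tids[0],
                frame=int(m["frame"]),
                nt_start=int(m["nt_start"]),
                nt_end=int(m["nt_end"]),
                aa_sequence=str(rec.seq),
                codon_count=int(m["codon_count"]),
                biotype=bts[0],
                gene_name="",
                provenance=list(zip(tids, bts)),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# PSM tables

DEFAULT_PSM_COLUMNS = {
    "sample_id": "sample_id",
    "spectrum_id": "spectrum_id",
    "peptide": "peptide",
    "q_value": "q_value",
    "score": "score",
}


def read_psm_table(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[PsmRecord]:
    """Read a PSM TSV into :class:`PsmRecord` objects.

    ``column_map`` maps the five logical fields (sample_id, spectrum_id,
    peptide, q_value, score) onto the file's column names; the upstream
    search engine's report columns vary, so this is explicit rather than
    guessed. Any row with a q-value outside [0, 1] rejects the whole file
    (a malformed export should not be half-read). Duplicate
    (sample_id, spectrum_id) pairs are kept — each row is one spectrum
    match — with a warning.
    """
    cmap = dict(DEFAULT_PSM_COLUMNS if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in (cmap["sample_id"], cmap["spectrum_id"], cmap["peptide"])})
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ConfigError(
            f"mapped columns {missing} not in PSM table; available columns: {list(df.columns)}"
        )
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        q = float(row_d[cmap["q_value"]])
        if not 0.0 <= q <= 1.0:
            raise FormatError(f"{path} line {i}: q_value {q} outside [0, 1]")
        records.append(
            PsmRecord(
                sample_id=str(row_d[cmap["sample_id"]]),
                spectrum_id=str(row_d[cmap["spectrum_id"]]),
                peptide=str(row_d[cmap["peptide"]]).upper(),
                q_value=q,
                score=float(row_d[cmap["score"]]),
            )
        )
    dup = df.duplicated(subset=[cmap["sample_id"], cmap["spectrum_id"]]).sum()
    if dup:
        logger.warning("%d duplicated (sample_id, spectrum_id) pairs kept in %s", dup, path)
    return records


def write_psm_table(psms: Sequence[PsmRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in psms],
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "q_value": [p.q_value for p in psms],
            "score": [p.score for p in psms],
            "assignment": [p.assignment for p in psms],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design tables


def read_design_table(path: str | Path) -> list[CohortDesign]:
    """Read a cohort design TSV (sample_id, group, pool_size, stratum_id, cohort)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "pool_size"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ConfigError(f"design table missing columns {missing}")
    design = [
        CohortDesign(
            sample_id=row["sample_id"],
            group=row["group"],
            pool_size=int(row["pool_size"]),
            stratum_id=(row.get("stratum_id") if isinstance(row.get("stratum_id"), str) else None),
            cohort=row.get("cohort") if isinstance(row.get("cohort"), str) else "newly_diagnosed",
        )
        for row in df.to_dict("records")
    ]
    validate_design(design)
    return design


def write_design_table(design: Sequence[CohortDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "group": [d.group for d in design],
            "pool_size": [d.pool_size for d in design],
            "stratum_id": [d.stratum_id if d.stratum_id is not None else "" for d in design],
            "cohort": [d.cohort for d in design],
        }
    ).to_csv(path, sep="\t", index=False)
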