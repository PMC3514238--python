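"""Reading and normalising peptide-spectrum matches (PSMs).

PSMs arrive either as tab-separated text (one row per match, configurable
column names) or as an mzIdentML 1.1 identification list. Internally every
score is oriented so that higher means better: files whose search engine
reports lower-is-better scores (e-value-like) are negated at read time.
"""
from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field

from lxml import etree

from .errors import FormatError, NormalizationError, RowError

#: sentinel for "no score available" (mzIdentML items without a score cvParam)
SCORE_NA = float("nan")

_FLANK_RE = re.compile(r"^([A-Za-z])\.(.+)\.([A-Za-z])$")
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")
_PEPTIDE_RE = re.compile(r"^[A-Z]+$")

DEFAULT_COLUMNS = {
    "spectrum": "spectrum",
    "peptide": "peptide",
    "charge": "charge",
    "score": "score",
    "proteins": "proteins",
}


@dataclass
class PSM:
    """One peptide-spectrum match.

    ``score`` is always oriented higher-is-better; ``protein_refs`` holds the
    search engine's protein accessions (possibly empty — such PSMs simply
    skip the annotation-filtered mapping pass).
    """

    spectrum_query: str
    peptide: str
    charge: int
    score: float
    protein_refs: list[str] = field(default_factory=list)
    source_row: int = -1

    def __post_init__(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(f"invalid peptide sequence {self.peptide!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        # keep first occurrence of each accession, drop duplicates
        seen: set[str] = set()
        self.protein_refs = [
            r for r in self.protein_refs if not (r in seen or seen.add(r))
        ]


def normalize_peptide(raw: str) -> str:
    """Reduce a search-engine peptide string to bare amino-acid letters.

    Strips single-letter flanking-residue notation (``K.PEPTIDER.A``),
    removes bracketed/parenthesised modification annotations and any
    remaining non-letter characters, and uppercases. A dot that survives
    flank stripping is rejected rather than silently removed.
    """
    s = raw.strip()
    if not s:
        raise NormalizationError("empty peptide string")
    m = _FLANK_RE.match(s)
    if m:
        s = m.group(2)
    s = _MOD_RE.sub("", s)
    if "." in s:
        raise NormalizationError(f"unexpected '.' in peptide {raw!r}")
    s = re.sub(r"[^A-Za-z]", "", s).upper()
    if not s:
        raise NormalizationError(f"peptide {raw!r} empty after normalization")
    return s


def read_psm_tsv(
    path,
    columns: dict[str, str] | None = None,
    score_direction: str = "higher_better",
) -> list[PSM]:
    """Read PSMs from tab-separated text.

    ``columns`` maps the logical names (spectrum, peptide, charge, score,
    proteins) onto the file's header names; the proteins cell is a
    ``;``-separated accession list. ``score_direction='lower_better'``
    negates scores so that higher is better internally.
    """
    if score_direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown score_direction {score_direction!r}")
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    psms: list[PSM] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        index: dict[str, int] = {}
        for logical, name in cols.items():
            if name not in header:
                raise FormatError(f"{path}: missing column {name!r}")
            index[logical] = header.index(name)
        for rowno, row in enumerate(reader, start=1):
            if not row or all(not c for c in row):
                continue
            try:
                charge = int(row[index["charge"]])
            except ValueError:
                raise RowError(rowno, f"non-numeric charge {row[index['charge']]!r}")
            try:
                score = float(row[index["score"]])
            except ValueError:
                raise RowError(rowno, f"non-numeric score {row[index['score']]!r}")
            if score_direction == "lower_better":
                score = -score
            prot_cell = row[index["proteins"]]
            refs = [p for p in prot_cell.split(";") if p]
            psms.append(
                PSM(
                    spectrum_query=row[index["spectrum"]],
                    peptide=normalize_peptide(row[index["peptide"]]),
                    charge=charge,
                    score=score,
                    protein_refs=refs,
                    source_row=rowno,
                )
            )
    return psms


def write_psm_tsv(psms: list[PSM], path, columns: dict[str, str] | None = None) -> None:
    """Write PSMs as tab-separated text (inverse of :func:`read_psm_tsv`)."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([cols[k] for k in ("spectrum", "peptide", "charge", "score", "proteins")])
        for p in psms:
            writer.writerow(
                [p.spectrum_query, p.peptide, p.charge, repr(p.score), ";".join(p.protein_refs)]
            )


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_psm_mzid(path, score_name: str | None = None) -> list[PSM]:
    """Read PSMs from an mzIdentML 1.1 identification list.

    Only the identification subset is consumed: Peptide / PeptideEvidence /
    DBSequence from the SequenceCollection and SpectrumIdentificationResult
    items. The score is taken from the cvParam named ``score_name`` when
    given, else from the first cvParam whose name contains "score"; items
    without any score keep ``SCORE_NA`` and trigger a warning.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()

    peptides: dict[str, str] = {}
    dbseqs: dict[str, str] = {}
    evidences: dict[str, dict] = {}
    for elem in root.iter():
        tag = _local(elem.tag)
        if tag == "Peptide":
            seq = ""
            for child in elem:
                if _local(child.tag) == "PeptideSequence":
                    seq = (child.text or "").strip()
            peptides[elem.get("id")] = seq
        elif tag == "DBSequence":
            dbseqs[elem.get("id")] = elem.get("accession", elem.get("id"))
        elif tag == "PeptideEvidence":
            evidences[elem.get("id")] = {
                "peptide_ref": elem.get("peptide_ref"),
                "dbseq_ref": elem.get("dBSequence_ref"),
            }

    psms: list[PSM] = []
    n = 0
    for result in root.iter():
        if _local(result.tag) != "SpectrumIdentificationResult":
            continue
        spectrum = result.get("spectrumID", result.get("id"))
        # prefer the spectrum title cvParam when present
        for child in result:
            if _local(child.tag) == "cvParam" and child.get("name") == "spectrum title":
                spectrum = child.get("value", spectrum)
        for item in result:
            if _local(item.tag) != "SpectrumIdentificationItem":
                continue
            n += 1
            pep_ref = item.get("peptide_ref")
            if pep_ref not in peptides:
                raise FormatError(f"{path}: dangling Peptide reference {pep_ref!r}")
            refs: list[str] = []
            score = SCORE_NA
            for child in item:
                tag = _local(child.tag)
                if tag == "PeptideEvidenceRef":
                    ev_ref = child.get("peptideEvidence_ref")
                    if ev_ref not in evidences:
                        raise FormatError(
                            f"{path}: dangling PeptideEvidence reference {ev_ref!r}"
                        )
                    db_ref = evidences[ev_ref]["dbseq_ref"]
                    if db_ref not in dbseqs:
                        raise FormatError(
                            f"{path}: dangling DBSequence reference {db_ref!r}"
                        )
                    refs.append(dbseqs[db_ref])
                elif tag == "cvParam":
                    name = child.get("name", "")
                    value = child.get("value")
                    if value is None:
                        continue
                    is_score = (
                        name == score_name
                        if score_name is not None
                        else "score" in name.lower()
                    )
                    if is_score and math.isnan(score):
                        try:
                            score = float(value)
                        except ValueError:
                            pass
            if math.isnan(score):
                warnings.warn(
                    f"{path}: no score cvParam on item {item.get('id')!r}; "
                    "score set to not-available"
                )
            psms.append(
                PSM(
                    spectrum_query=spectrum,
                    peptide=normalize_peptide(peptides[pep_ref]),
                    charge=int(item.get("chargeState", "1")),
                    score=score,
                    protein_refs=refs,
                    source_row=n,
                )
            )
    return psms
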