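"""Serialisation of peptide mappings as genome-browser tracks.

BED12 carries uniqueness as separate track sections and the score tier as
an itemRgb colour; GFF3 carries both in the feature type name
(``unique_high_peptide`` etc.) with one ``peptide_part`` child per spliced
block. BED is 0-based half-open, GFF3 1-based inclusive — the only place
in the package where a coordinate convention changes.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .mapping_engine import PASS_ANNOTATION, PASS_SEQUENCE, PeptideMapping

DEFAULT_COLORS = {
    "low": (128, 128, 128),   # grey
    "mid": (255, 140, 0),     # orange
    "high": (0, 170, 0),      # green
}
DEFAULT_BED_SCORES = {"low": 333, "mid": 666, "high": 1000}


@dataclass
class TrackConfig:
    track_basename: str = "peptides"
    colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    bed_score: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BED_SCORES))
    split_by_pass: bool = True

    def __post_init__(self) -> None:
        for tier in ("low", "mid", "high"):
            if tier not in self.colors:
                raise ValueError(f"no color configured for tier {tier!r}")


def _best_psm(mp: PeptideMapping):
    best = None
    for p in mp.psms:
        if best is None or (
            not math.isnan(p.score) and (math.isnan(best.score) or p.score > best.score)
        ):
            best = p
    return best


def _bed_name(mp: PeptideMapping) -> str:
    psm = _best_psm(mp)
    query = psm.spectrum_query if psm else "NA"
    charge = psm.charge if psm else 0
    name = (
        f"{mp.peptide}|gene={mp.gene}|q={query}|z={charge}"
        f"|shared={mp.shared_count}|pass={mp.mapping_pass}"
    )
    return re.sub(r"\s", "_", name)  # BED names must not contain whitespace


def _bed_line(mp: PeptideMapping, cfg: TrackConfig) -> str:
    blocks = mp.blocks.blocks
    start, end = mp.blocks.start, mp.blocks.end
    sizes = ",".join(str(e - s) for s, e in blocks)
    rel_starts = ",".join(str(s - start) for s, _ in blocks)
    rgb = ",".join(str(c) for c in cfg.colors[mp.tier])
    fields = [
        mp.chrom,
        str(start),
        str(end),
        _bed_name(mp),
        str(cfg.bed_score[mp.tier]),
        mp.strand,
        str(start),
        str(end),
        rgb,
        str(len(blocks)),
        sizes,
        rel_starts,
    ]
    return "\t".join(fields)


def _sections(cfg: TrackConfig) -> list[tuple[str, callable]]:
    if cfg.split_by_pass:
        return [
            (f"unique_{p}", lambda mp, u=True, p=p: mp.unique is u and mp.mapping_pass == p)
            for p in (PASS_ANNOTATION, PASS_SEQUENCE)
        ] + [
            (f"shared_{p}", lambda mp, u=False, p=p: mp.unique is u and mp.mapping_pass == p)
            for p in (PASS_ANNOTATION, PASS_SEQUENCE)
        ]
    return [
        ("unique", lambda mp: mp.unique),
        ("shared", lambda mp: not mp.unique),
    ]


def write_bed(mappings: list[PeptideMapping], cfg: TrackConfig, path) -> None:
    """Write classified mappings as BED12 with one track section per
    uniqueness class (and per mapping pass when ``split_by_pass``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for section, predicate in _sections(cfg):
            fh.write(
                f'track name="{cfg.track_basename}_{section}" '
                f'description="peptide mappings ({section.replace("_", ", ")})" '
                f"itemRgb=On\n"
            )
            selected = sorted(
                (mp for mp in mappings if predicate(mp)),
                key=lambda mp: (mp.chrom, mp.blocks.start, mp.peptide, mp.gene),
            )
            for mp in selected:
                fh.write(_bed_line(mp, cfg) + "\n")


_GFF3_ESCAPE = {
    "%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
    "\t": "%09", "\n": "%0A", "\r": "%0D",
}


def gff3_escape(value: str) -> str:
    return "".join(_GFF3_ESCAPE.get(c, c) for c in str(value))


def write_gff3(mappings: list[PeptideMapping], cfg: TrackConfig, path) -> None:
    """Write classified mappings as GFF3: one parent feature per mapping
    (type ``<uniqueness>_<tier>_peptide``) plus a ``peptide_part`` child per
    spliced block."""
    source = cfg.track_basename
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        ordered = sorted(
            mappings, key=lambda mp: (mp.chrom, mp.blocks.start, mp.peptide, mp.gene)
        )
        for i, mp in enumerate(ordered, start=1):
            psm = _best_psm(mp)
            ftype = f"{'unique' if mp.unique else 'shared'}_{mp.tier}_peptide"
            best = mp.best_score()
            score = f"{best:g}" if best != float("-inf") else "."
            feature_id = f"pep{i:06d}"
            attrs = ";".join(
                f"{k}={gff3_escape(v)}"
                for k, v in [
                    ("ID", feature_id),
                    ("Name", mp.peptide),
                    ("gene", mp.gene),
                    ("spectrum", psm.spectrum_query if psm else "NA"),
                    ("charge", psm.charge if psm else 0),
                    ("shared_count", mp.shared_count),
                    ("mapping_pass", mp.mapping_pass),
                    ("score", score),
                ]
            )
            fh.write(
                "\t".join(
                    [
                        mp.chrom, source, ftype,
                        str(mp.blocks.start + 1), str(mp.blocks.end),
                        score, mp.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for j, (s, e) in enumerate(mp.blocks.blocks, start=1):
                child_attrs = f"ID={feature_id}.part{j};Parent={feature_id}"
                fh.write(
                    "\t".join(
                        [
                            mp.chrom, source, "peptide_part",
                            str(s + 1), str(e),
                            score, mp.strand, ".", child_attrs,
                        ]
                    )
                    + "\n"
                )


def write_unmapped(peptides: list[tuple[str, list]], path) -> None:
    """Write the unmapped-peptide report: one TSV row per peptide with its
    supporting spectrum queries and best score, sorted by peptide."""
    merged: dict[str, list] = {}
    for pep, psms in peptides:
        merged.setdefault(pep, []).extend(psms)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tspectrum_queries\tbest_score\n")
        for pep in sorted(merged):
            psms = merged[pep]
            queries = ";".join(p.spectrum_query for p in psms)
            scores = [p.score for p in psms if not math.isnan(p.score)]
            best = f"{max(scores):g}" if scores else "NA"
            fh.write(f"{pep}\t{queries}\t{best}\n")
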