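"""TSV readers/writers with validation and provenance.

All tables are UTF-8 TSV with a mandatory header row; lines starting with
``#`` are comments, and every file the package writes begins with a
provenance header (tool version, input digests, parameters, seed) so runs
can be audited and diffed.  Gzip-compressed inputs are accepted
transparently (sniffed by magic bytes, not extension).  Malformed rows are
reported with their line number.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import yaml

from . import __version__
from .assoc import BipartiteEdges, OverlapScore, ScoredPairList
from .drug_target import ActivityRecord, EnrichmentResult
from .errors import InputFormatError
from .pheno_target import (
    FUNFAM_ID_RE,
    HPO_ID_RE,
    DiseaseAnnotations,
    GeneDomainMap,
)
from .validation import CooccurrenceRecord, GoldStandard, ValidationReport

PAIR_COLUMNS = ("a_id", "b_id", "k", "size_a", "size_b", "N",
                "p_value", "hyi")
ACTIVITY_COLUMNS = ("drug_id", "target_id", "therapeutic_flag", "assay_type",
                    "relationship_type", "target_type", "pchembl")


def _open_text(path: str | Path) -> TextIO:
    """Open a text file, decompressing gzip transparently (magic sniffed)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _rows(path: str | Path, required: Sequence[str]):
    """Yield (line_number, dict) for each data row; validate the header."""
    with _open_text(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise InputFormatError(
                        f"{path}: missing required column(s) "
                        f"{', '.join(missing)}")
                continue
            if len(fields) != len(header):
                raise InputFormatError(
                    f"{path}: line {lineno}: expected {len(header)} "
                    f"columns, found {len(fields)}")
            yield lineno, dict(zip(header, fields))
        if header is None:
            raise InputFormatError(f"{path}: empty file, header required")


def _validate_id(path, lineno, value: str, kind: str) -> str:
    if not value:
        raise InputFormatError(f"{path}: line {lineno}: empty {kind} ID")
    if kind == "hpo" and not HPO_ID_RE.match(value):
        raise InputFormatError(
            f"{path}: line {lineno}: malformed HPO ID {value!r}")
    if kind == "funfam" and not FUNFAM_ID_RE.match(value):
        raise InputFormatError(
            f"{path}: line {lineno}: malformed FunFam ID {value!r}")
    return value


def read_edges(path: str | Path, outer_col: str, middle_col: str,
               outer_role: str, middle_role: str,
               outer_kind: str = "plain",
               middle_kind: str = "plain") -> BipartiteEdges:
    """Read a two-column edge list into :class:`BipartiteEdges`.

    ``outer_kind``/``middle_kind`` select the ID validator: ``"plain"``,
    ``"hpo"`` or ``"funfam"``.
    """
    pairs = []
    for lineno, row in _rows(path, (outer_col, middle_col)):
        o = _validate_id(path, lineno, row[outer_col], outer_kind)
        m = _validate_id(path, lineno, row[middle_col], middle_kind)
        pairs.append((o, m))
    return BipartiteEdges.from_pairs(pairs, outer_role, middle_role)


def read_disease_annotations(disease_gene_path, disease_phenotype_path,
                             source_label: str = "omim-like"
                             ) -> DiseaseAnnotations:
    """Read disease_gene.tsv (disease_id, gene_id) and
    disease_phenotype.tsv (disease_id, hpo_id)."""
    dg = read_edges(disease_gene_path, "gene_id", "disease_id",
                    "gene", "disease")
    dp = read_edges(disease_phenotype_path, "hpo_id", "disease_id",
                    "phenotype", "disease", outer_kind="hpo")
    return DiseaseAnnotations(dg, dp, source_label)


def read_gene_funfam(path) -> GeneDomainMap:
    """Read gene_funfam.tsv (gene_id, funfam_id)."""
    return GeneDomainMap(read_edges(path, "gene_id", "funfam_id",
                                    "gene", "funfam",
                                    middle_kind="funfam"))


def read_activities(path) -> list[ActivityRecord]:
    """Read activities.tsv with the ChEMBL-style activity columns; an empty
    pchembl field is read as missing."""
    records = []
    for lineno, row in _rows(path, ACTIVITY_COLUMNS):
        try:
            pchembl = float(row["pchembl"]) if row["pchembl"] != "" else None
            records.append(ActivityRecord(
                drug_id=_validate_id(path, lineno, row["drug_id"], "plain"),
                target_id=_validate_id(path, lineno, row["target_id"],
                                       "plain"),
                therapeutic_flag=int(row["therapeutic_flag"]),
                assay_type=row["assay_type"],
                relationship_type=row["relationship_type"],
                target_type=row["target_type"],
                pchembl=pchembl,
            ))
        except ValueError as exc:
            raise InputFormatError(
                f"{path}: line {lineno}: {exc}") from exc
    return records


def read_gold(path) -> GoldStandard:
    """Read gold.tsv (hpo_id, drug_id)."""
    pairs = set()
    for lineno, row in _rows(path, ("hpo_id", "drug_id")):
        h = _validate_id(path, lineno, row["hpo_id"], "hpo")
        d = _validate_id(path, lineno, row["drug_id"], "plain")
        pairs.add((h, d))
    return GoldStandard(frozenset(pairs))


def read_comentions(path) -> list[CooccurrenceRecord]:
    """Read comentions.tsv (drug_id, hpo_id, n_drug, n_hpo, n_both,
    n_total)."""
    records = []
    cols = ("drug_id", "hpo_id", "n_drug", "n_hpo", "n_both", "n_total")
    for lineno, row in _rows(path, cols):
        try:
            records.append(CooccurrenceRecord(
                drug_id=row["drug_id"],
                hpo_id=_validate_id(path, lineno, row["hpo_id"], "hpo"),
                n_drug=int(row["n_drug"]),
                n_hpo=int(row["n_hpo"]),
                n_both=int(row["n_both"]),
                n_total=int(row["n_total"]),
            ))
        except ValueError as exc:
            raise InputFormatError(
                f"{path}: line {lineno}: {exc}") from exc
    return records


def read_umls_hpo_map(path) -> dict[str, str]:
    """Read umls_hpo_map.tsv (umls_id, hpo_id) into a mapping."""
    mapping = {}
    for lineno, row in _rows(path, ("umls_id", "hpo_id")):
        mapping[row["umls_id"]] = _validate_id(
            path, lineno, row["hpo_id"], "hpo")
    return mapping


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for provenance headers."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_lines(params: Mapping[str, object] | None = None,
                     inputs: Mapping[str, str | Path] | None = None,
                     seed: Optional[int] = None) -> list[str]:
    """Comment lines recording how an output was produced.

    Deliberately timestamp-free so identical runs write identical bytes.
    """
    lines = [f"# drugeff {__version__}"]
    if inputs:
        for name, path in sorted(inputs.items()):
            lines.append(f"# input {name}={Path(path).name} "
                         f"sha256={file_digest(path)}")
    if params:
        for key, value in sorted(params.items()):
            lines.append(f"# param {key}={value}")
    if seed is not None:
        lines.append(f"# param seed={seed}")
    return lines


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_pairs(pairs: ScoredPairList, path: str | Path,
                provenance: Optional[list[str]] = None) -> None:
    """Write a scored pair list in the standard schema (full precision, so
    a read-back reproduces scores bit-identically)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        if pairs.threshold_applied is not None:
            fh.write(f"# param threshold_applied="
                     f"{pairs.threshold_applied}\n")
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for s in pairs:
            fh.write("\t".join((
                s.a_id, s.b_id, str(s.k), str(s.size_a), str(s.size_b),
                str(s.N), _fmt(s.p_value), _fmt(s.hyi))) + "\n")


def read_pairs(path: str | Path) -> ScoredPairList:
    """Read back a scored pair list written by :func:`write_pairs`."""
    threshold = None
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("# param threshold_applied="):
                threshold = float(line.strip().split("=", 1)[1])
    scores = []
    for lineno, row in _rows(path, PAIR_COLUMNS):
        try:
            scores.append(OverlapScore(
                a_id=row["a_id"], b_id=row["b_id"], N=int(row["N"]),
                size_a=int(row["size_a"]), size_b=int(row["size_b"]),
                k=int(row["k"]), p_value=float(row["p_value"]),
                hyi=float(row["hyi"])))
        except ValueError as exc:
            raise InputFormatError(f"{path}: line {lineno}: {exc}") from exc
    return ScoredPairList(tuple(scores), threshold_applied=threshold)


def write_edges(edges: BipartiteEdges, path: str | Path,
                outer_col: str, middle_col: str,
                provenance: Optional[list[str]] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write(f"{outer_col}\t{middle_col}\n")
        for o, m in sorted(edges.edges):
            fh.write(f"{o}\t{m}\n")


def write_activities(records: Iterable[ActivityRecord], path: str | Path,
                     provenance: Optional[list[str]] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write("\t".join(ACTIVITY_COLUMNS) + "\n")
        for r in records:
            pch = "" if r.pchembl is None else _fmt(r.pchembl)
            fh.write("\t".join((
                r.drug_id, r.target_id, str(r.therapeutic_flag),
                r.assay_type, r.relationship_type, r.target_type,
                pch)) + "\n")


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path,
                     provenance: Optional[list[str]] = None) -> None:
    """Write drug_funfam.tsv (drug_id, funfam_id, n, x, q, p_value)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write("drug_id\tfunfam_id\tn\tx\tq\tp_value\n")
        for r in results:
            fh.write("\t".join((
                r.drug_id, r.funfam_id, str(r.n), str(r.x),
                _fmt(r.q), _fmt(r.p_value))) + "\n")


def write_validation_reports(reports: Iterable[ValidationReport],
                             path: str | Path,
                             provenance: Optional[list[str]] = None) -> None:
    """One row per threshold: confirmed, randomized mean +- sd, ratio."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write("threshold\tconfirmed\trandom_mean\trandom_sd\tratio"
                 "\tn_replicates\tseed\n")
        for r in reports:
            ratio = "inf" if math.isinf(r.ratio) else _fmt(r.ratio)
            fh.write("\t".join((
                _fmt(r.threshold), str(r.confirmed), _fmt(r.random_mean),
                _fmt(r.random_sd), ratio, str(r.n_replicates),
                str(r.seed))) + "\n")


def write_gold(gold: GoldStandard, path: str | Path,
               provenance: Optional[list[str]] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write("hpo_id\tdrug_id\n")
        for h, d in sorted(gold.pairs):
            fh.write(f"{h}\t{d}\n")


def write_comentions(records: Iterable[CooccurrenceRecord],
                     path: str | Path,
                     provenance: Optional[list[str]] = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or []:
            fh.write(line + "\n")
        fh.write("drug_id\thpo_id\tn_drug\tn_hpo\tn_both\tn_total\n")
        for r in records:
            fh.write("\t".join((
                r.drug_id, r.hpo_id, str(r.n_drug), str(r.n_hpo),
                str(r.n_both), str(r.n_total))) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a flat dict."""
    with _open_text(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InputFormatError(f"{path}: config must be a YAML mapping")
    return data
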