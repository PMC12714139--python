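"""Domain containers, validation and file I/O.

The pipeline works on five kinds of input, all plain text:

* an abundance matrix (TSV, metabolites x samples) plus a sample sheet
  (CSV) describing each column, including extraction blanks;
* pathway membership maps in GMT format;
* per-individual survival tables (CSV);
* qPCR cycle-threshold tables (CSV);
* a run configuration (YAML or JSON).

Containers are thin dataclasses around pandas/numpy objects and validate
their invariants on construction.  Readers raise :class:`ValidationError`
(malformed content) or :class:`ParseError` (malformed syntax) with enough
context to locate the offending record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("planmet")

TISSUES = ("brain", "gut", "muscle", "whole")
TREATMENTS = ("control", "DA")

SHEET_COLUMNS = ("sample_id", "tissue", "genotype", "treatment",
                 "age_days", "replicate", "is_blank")
SURVIVAL_COLUMNS = ("individual_id", "group", "time", "status")
CT_COLUMNS = ("sample_id", "gene", "role", "ct", "treatment",
              "age_days", "replicate")


class PipelineError(Exception):
    """Base class for all planmet errors."""


class ValidationError(PipelineError):
    """Input content violates a container invariant."""


class ParseError(PipelineError):
    """Input file is syntactically malformed."""


class ConfigError(PipelineError):
    """Run or generator configuration is inconsistent."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    Non-blank rows must carry a known tissue/treatment, a positive age and
    replicate, and a design position (tissue, genotype, treatment, age,
    replicate) that is unique.  Blank rows (``is_blank`` true) carry no
    biological semantics and are exempt.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["is_blank"] = sheet["is_blank"].astype(bool)
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    study = sheet[~sheet["is_blank"]]
    bad_tissue = set(study["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(
            f"unknown tissue values {sorted(bad_tissue)}; expected {TISSUES}")
    bad_treat = set(study["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ValidationError(
            f"unknown treatment values {sorted(bad_treat)}; "
            f"expected {TREATMENTS}")
    if len(study):
        ages = pd.to_numeric(study["age_days"], errors="raise")
        if (ages <= 0).any():
            raise ValidationError("age_days must be positive")
        reps = pd.to_numeric(study["replicate"], errors="raise")
        if (reps <= 0).any():
            raise ValidationError("replicate must be positive")
        key = study[["tissue", "genotype", "treatment", "age_days",
                     "replicate"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate design positions: {dups[:5]}")
    return sheet.set_index("sample_id", drop=False)


@dataclass
class AbundanceMatrix:
    """Metabolite x sample intensity matrix with linked sample annotations.

    ``intensities[i, j]`` is the measured abundance of ``metabolite_ids[i]``
    in ``sample_ids[j]`` in arbitrary instrument units; a missing
    measurement is recorded as 0.  ``stage`` tracks preprocessing: raw
    matrices must be non-negative, while ``log10``/``uv`` matrices may hold
    any finite value.
    """

    metabolite_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    sample_sheet: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.intensities.shape != (len(self.metabolite_ids),
                                      len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.intensities.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x "
                f"{len(self.sample_ids)} samples")
        if not np.isfinite(self.intensities).all():
            raise ValidationError("non-finite intensity")
        if self.stage == "raw" and (self.intensities < 0).any():
            bad = np.argwhere(self.intensities < 0)[0]
            raise ValidationError(
                "negative intensity at metabolite "
                f"{self.metabolite_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}")
        if "sample_id" in getattr(self.sample_sheet, "columns", []):
            if self.sample_sheet.index.name != "sample_id":
                self.sample_sheet = validate_sample_sheet(self.sample_sheet)
        unresolved = [s for s in self.sample_ids
                      if s not in self.sample_sheet.index]
        if unresolved:
            raise ValidationError(
                f"samples absent from sample sheet: {unresolved[:10]}")

    # convenience views -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.metabolite_ids,
                            columns=self.sample_ids)

    @property
    def sheet(self) -> pd.DataFrame:
        """Sheet rows for the samples present, in matrix column order."""
        return self.sample_sheet.loc[self.sample_ids]

    def blank_mask(self) -> np.ndarray:
        return self.sheet["is_blank"].to_numpy(dtype=bool)

    def subset(self, metabolites: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "AbundanceMatrix":
        met = list(metabolites) if metabolites is not None else self.metabolite_ids
        sam = list(samples) if samples is not None else self.sample_ids
        mi = [self.metabolite_ids.index(m) for m in met]
        si = [self.sample_ids.index(s) for s in sam]
        return AbundanceMatrix(met, sam, self.intensities[np.ix_(mi, si)],
                               self.sample_sheet, stage=self.stage)

    def with_values(self, values: np.ndarray, stage: str) -> "AbundanceMatrix":
        return AbundanceMatrix(list(self.metabolite_ids),
                               list(self.sample_ids), values,
                               self.sample_sheet, stage=stage)


@dataclass
class PathwayMap:
    """Pathway id -> set of member metabolite ids (a metabolite may appear
    in several pathways)."""

    members: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValidationError(f"pathway {pid!r} has no members")

    def restricted_to(self, panel: Iterable[str]) -> "PathwayMap":
        """Intersect every member set with the measured panel, dropping
        pathways left empty (a notice is logged for each)."""
        panel = set(panel)
        kept: dict[str, set[str]] = {}
        for pid, mem in self.members.items():
            inter = mem & panel
            if inter:
                kept[pid] = inter
            else:
                logger.info("pathway %s has no measured members; omitted", pid)
        return PathwayMap(kept, {p: d for p, d in self.descriptions.items()
                                 if p in kept})


def validate_survival(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"survival table missing columns: {missing}")
    records = records.copy()
    records["time"] = pd.to_numeric(records["time"], errors="raise")
    if not np.isfinite(records["time"]).all() or (records["time"] <= 0).any():
        raise ValidationError("survival times must be positive and finite")
    bad = set(records["status"]) - {"dead", "censored"}
    if bad:
        raise ValidationError(f"unknown status values: {sorted(bad)}")
    return records


def validate_ct(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    table = table.copy()
    table["ct"] = pd.to_numeric(table["ct"], errors="raise")
    if not np.isfinite(table["ct"]).all():
        raise ValidationError("non-finite Ct value")
    bad = set(table["role"]) - {"target", "reference"}
    if bad:
        raise ValidationError(f"unknown role values: {sorted(bad)}")
    # every (condition, replicate) with a target well needs a reference well
    key = ["treatment", "age_days", "replicate"]
    tgt = set(map(tuple, table.loc[table["role"] == "target", key].values))
    ref = set(map(tuple, table.loc[table["role"] == "reference", key].values))
    orphan = tgt - ref
    if orphan:
        raise ValidationError(
            f"target wells without a reference well: {sorted(orphan)[:5]}")
    return table


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide settings plus the synthetic-generator parameters.

    ``generator``, ``survival`` and ``qpcr`` hold the keyword arguments of
    the corresponding :mod:`planmet.simulate` entry points; they are kept
    as plain dicts so a YAML config maps onto them directly.
    """

    seed: int = 0
    alpha: float = 0.05
    blank_fold: float = 5.0
    cv_folds: int = 7
    n_components: int | None = None     # None = choose by Q2(cum), cap 5
    enrichment_convention: str = "literal"
    generator: dict[str, Any] = field(default_factory=dict)
    survival: dict[str, Any] = field(default_factory=dict)
    qpcr: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.blank_fold <= 0:
            raise ConfigError("blank_fold must be positive")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.enrichment_convention not in ("literal", "standard"):
            raise ConfigError(
                "enrichment_convention must be 'literal' or 'standard'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if raw is None:
        raw = {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_abundance(matrix_path: str | Path,
                   sheet_path: str | Path) -> AbundanceMatrix:
    """Read a TSV abundance matrix plus its CSV sample sheet.

    The TSV carries metabolite ids in the first column and sample ids in
    the header.  Samples present in the sheet but not the matrix are
    reported (logged), not fatal; a matrix sample missing from the sheet is
    a validation error.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = validate_sample_sheet(pd.read_csv(sheet_path))
    unreferenced = sorted(set(sheet.index) - set(frame.columns))
    if unreferenced:
        logger.warning("sheet samples absent from matrix: %s", unreferenced)
    return AbundanceMatrix(
        metabolite_ids=[str(m) for m in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        intensities=frame.to_numpy(dtype=float),
        sample_sheet=sheet,
    )


def read_gmt(path: str | Path) -> PathwayMap:
    """Read a GMT pathway file: ``pathway_id<TAB>description<TAB>member...``.

    Duplicate members within a line are collapsed; a line with fewer than
    three fields is a parse error naming the line number.
    """
    members: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            pid, desc, *mem = fields
            members[pid] = set(m for m in mem if m)
            descriptions[pid] = desc
    return PathwayMap(members, descriptions)


def read_survival(path: str | Path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path))


def read_ct(path: str | Path) -> pd.DataFrame:
    return validate_ct(pd.read_csv(path))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(str(v) for v in obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_report(results: Any, path: str | Path) -> None:
    """Write a stage output: DataFrames as full-precision TSV, mappings and
    dataclasses as sorted-key JSON.  Re-reading reproduces the values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, AbundanceMatrix):
        results.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    elif isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_abundance(matrix: AbundanceMatrix, matrix_path: str | Path,
                    sheet_path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "metabolite_id"
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    matrix.sheet.to_csv(sheet_path, index=False)


def write_gmt(pathways: PathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pathways.members):
            desc = pathways.descriptions.get(pid, "")
            mem = "\t".join(sorted(pathways.members[pid]))
            fh.write(f"{pid}\t{desc}\t{mem}\n")


def write_run_summary(config: RunConfig, row_counts: Mapping[str, int],
                      path: str | Path) -> None:
    """JSON run summary: the seed, the full config, and per-table row
    counts, for provenance and determinism checks."""
    write_report({"seed": config.seed, "config": config.to_dict(),
                  "row_counts": dict(row_counts)}, path)
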