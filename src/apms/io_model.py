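"""Core data model and text-table I/O for AP-MS peak-volume analysis.

The elementary quantification unit is the peak volume (PV): a peptide's
m/z signal intensity integrated over chromatographic elution time. A
:class:`PVMatrix` holds PVs for many peptides across several affinity
purification (AP) datasets and is the universal input of the pipeline.

All tables are tab-separated UTF-8 text with '.' as decimal separator and
the empty string for missing values (missing is distinct from zero).
Floats are serialized with six significant digits, below measurement
precision, so read/write round-trips are stable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("apms")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
CONTROL_KINDS = ("none", "igg", "depletion", "knockout", "sh_control")
SERIAL_POSITIONS = ("first", "second", "not_serial")

#: printf-style format used for every float written to disk.
FLOAT_FMT = "%.6g"


class TableFormatError(ValueError):
    """A table file does not conform to the expected schema."""


class ValidationError(ValueError):
    """A value violates a data-model invariant."""


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideRecord:
    """One tryptic peptide assigned to exactly one protein accession.

    Peptides shared between isoforms are kept in the matrix but flagged,
    and excluded from isoform-specific quantification.
    """

    protein_id: str
    sequence: str
    is_isoform_specific: bool = True

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError("peptide sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.sequence!r} contains invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DatasetMeta:
    """Metadata for one AP dataset (one LC-MS run of one purification).

    ``control_kind`` distinguishes target APs (``none``) from the negative
    controls used for specificity calling: pre-immunization IgG, a
    target-depleted solubilisate, a knockout membrane fraction, or a
    control-shRNA culture. ``serial_position`` marks the two steps of a
    serial (two-step) AP pair.
    """

    dataset_id: str
    target_protein_ids: frozenset = frozenset()
    antibody_id: str = ""
    control_kind: str = "none"
    replicate_group: str = ""
    serial_position: str = "not_serial"

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValidationError("dataset_id must be non-empty")
        if self.control_kind not in CONTROL_KINDS:
            raise ValidationError(
                f"control_kind {self.control_kind!r} not one of {CONTROL_KINDS}"
            )
        if self.serial_position not in SERIAL_POSITIONS:
            raise ValidationError(
                f"serial_position {self.serial_position!r} not one of {SERIAL_POSITIONS}"
            )
        object.__setattr__(
            self, "target_protein_ids", frozenset(self.target_protein_ids)
        )
        if not self.target_protein_ids and self.control_kind != "igg":
            raise ValidationError(
                f"dataset {self.dataset_id!r}: an empty target set is only "
                "allowed for IgG controls"
            )


class PVMatrix:
    """Peptides x AP-datasets table of peak volumes.

    Parameters
    ----------
    peptides
        One :class:`PeptideRecord` per row of ``values``.
    values
        DataFrame indexed by peptide sequence with one float column per
        dataset; NaN encodes "not detected" (distinct from 0).
    datasets
        Optional per-dataset metadata. When given, its ids must match the
        columns of ``values`` exactly.
    """

    def __init__(
        self,
        peptides: Sequence[PeptideRecord],
        values: pd.DataFrame,
        datasets: Sequence[DatasetMeta] | None = None,
    ) -> None:
        peptides = list(peptides)
        seqs = [p.sequence for p in peptides]
        if len(set(seqs)) != len(seqs):
            dupes = sorted({s for s in seqs if seqs.count(s) > 1})
            raise ValidationError(f"duplicate peptide sequences: {dupes[:5]}")
        if list(values.index) != seqs:
            raise ValidationError("values index must equal the peptide sequences")
        if len(set(values.columns)) != len(values.columns):
            raise ValidationError("dataset ids must be unique")
        arr = values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("peak volumes must be finite")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("peak volumes must be >= 0")
        if datasets is not None:
            ids = [d.dataset_id for d in datasets]
            if ids != list(values.columns):
                raise ValidationError(
                    "dataset metadata ids must match value columns"
                )
            datasets = list(datasets)
        self.peptides = peptides
        self.values = values.astype(float)
        self.datasets = datasets

    # -- convenience views ---------------------------------------------------

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def protein_of(self) -> pd.Series:
        return pd.Series(
            {p.sequence: p.protein_id for p in self.peptides}, name="protein_id"
        ).reindex(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.peptides:
            seen.setdefault(p.protein_id, None)
        return list(seen)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_datasets(self) -> int:
        return self.values.shape[1]

    def specific_only(self) -> "PVMatrix":
        """Matrix restricted to isoform-specific peptides."""
        keep = [p for p in self.peptides if p.is_isoform_specific]
        seqs = [p.sequence for p in keep]
        return PVMatrix(keep, self.values.loc[seqs], self.datasets)

    def subset_datasets(self, ids: Sequence[str]) -> "PVMatrix":
        meta = None
        if self.datasets is not None:
            by_id = {d.dataset_id: d for d in self.datasets}
            meta = [by_id[i] for i in ids]
        return PVMatrix(self.peptides, self.values[list(ids)], meta)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PVMatrix({self.n_peptides} peptides x {self.n_datasets} datasets)"


class CalibrationTable:
    """Per-(protein, dataset) calibration abundances from standard peptides.

    Values are strictly positive; the label-free calibration scales a
    protein's relative profile to best fit these anchors.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]) -> None:
        clean: dict[tuple[str, str], float] = {}
        for (pid, did), v in entries.items():
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"calibration value for ({pid}, {did}) must be finite and >= 0"
                )
            clean[(str(pid), str(did))] = v
        self.entries = clean

    def proteins(self) -> list[str]:
        return sorted({pid for pid, _ in self.entries})

    def for_protein(self, protein_id: str) -> pd.Series:
        vals = {
            did: v for (pid, did), v in self.entries.items() if pid == protein_id
        }
        return pd.Series(vals, dtype=float).sort_index()

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline, all echoed into the run log.

    ``k_min``/``k_cap``/``fraction`` parameterize the best-correlating
    peptide-selection rule; ``threshold_multiplier`` scales the robust
    spread of the background log-ratio mode; ``imputation_factor`` sets
    the detection floor (fraction of the smallest observed abundance) for
    proteins undetected in a control.
    """

    k_min: int = 3
    k_cap: int | None = None
    fraction: float = 0.5
    min_shared: int = 3
    outlier_r_cutoff: float = 0.0
    threshold_multiplier: float = 3.0
    imputation_factor: float = 0.5
    n_antibody_min: int = 2
    seed: int = 0
    out_dir: str = "apms_out"

    def validate(self) -> "PipelineConfig":
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        if self.k_min < 1:
            raise ValidationError("k_min must be >= 1")
        if self.k_cap is not None and self.k_cap < self.k_min:
            raise ValidationError("k_cap must be >= k_min")
        if not 0 < self.fraction <= 1:
            raise ValidationError("fraction must be in (0, 1]")
        if self.min_shared < 2:
            raise ValidationError("min_shared must be >= 2")
        if self.threshold_multiplier <= 0:
            raise ValidationError("threshold_multiplier must be > 0")
        if not 0 < self.imputation_factor <= 1:
            raise ValidationError("imputation_factor must be in (0, 1]")
        if self.n_antibody_min < 1:
            raise ValidationError("n_antibody_min must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text) if text.strip() else {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise TableFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BOOL_TRUE = {"1", "true", "yes"}
_BOOL_FALSE = {"0", "false", "no"}
_META_COLUMNS = (
    "dataset_id",
    "target_protein_ids",
    "antibody_id",
    "control_kind",
    "replicate_group",
    "serial_position",
)


def _parse_bool(s: str, where: str) -> bool:
    t = s.strip().lower()
    if t in _BOOL_TRUE:
        return True
    if t in _BOOL_FALSE:
        return False
    raise TableFormatError(f"{where}: cannot parse boolean from {s!r}")


def read_pv_table(path: str | Path) -> PVMatrix:
    """Read a peptide PV table (MaxQuant-style peptide feature export).

    Required columns: ``protein_id``, ``sequence``, and one column per
    dataset; optional ``is_isoform_specific``. Empty cells are missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "sequence"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    has_flag = "is_isoform_specific" in df.columns
    reserved = {"protein_id", "sequence", "is_isoform_specific"}
    data_cols = [c for c in df.columns if c not in reserved]
    if not data_cols:
        raise TableFormatError(f"{path.name}: no dataset columns found")

    peptides: list[PeptideRecord] = []
    rows: list[list[float]] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = dict(zip(df.columns, rec))
        flag = _parse_bool(d["is_isoform_specific"], f"row {i}") if has_flag else True
        peptides.append(
            PeptideRecord(d["protein_id"].strip(), d["sequence"].strip(), flag)
        )
        vals: list[float] = []
        for c in data_cols:
            cell = d[c].strip()
            if cell == "":
                vals.append(math.nan)
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise TableFormatError(
                    f"{path.name} row {i}, column {c!r}: not a number: {cell!r}"
                ) from exc
            if v < 0:
                raise ValidationError(
                    f"{path.name} row {i}, column {c!r}: negative PV {v}"
                )
            vals.append(v)
        rows.append(vals)

    values = pd.DataFrame(
        rows, index=[p.sequence for p in peptides], columns=data_cols, dtype=float
    )
    return PVMatrix(peptides, values)


def write_pv_table(pv: PVMatrix, path: str | Path) -> None:
    path = Path(path)
    cols = ["protein_id", "sequence", "is_isoform_specific"] + pv.dataset_ids
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in pv.peptides:
            row = [p.protein_id, p.sequence, "1" if p.is_isoform_specific else "0"]
            row += [_fmt(v) for v in pv.values.loc[p.sequence]]
            fh.write("\t".join(row) + "\n")


def read_calibration_table(path: str | Path) -> CalibrationTable:
    """Read a calibration TSV with columns protein_id, dataset_id, value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "dataset_id", "value"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    entries: dict[tuple[str, str], float] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, rec))
        try:
            v = float(d["value"])
        except ValueError as exc:
            raise TableFormatError(
                f"{path.name} row {i}: not a number: {d['value']!r}"
            ) from exc
        entries[(d["protein_id"].strip(), d["dataset_id"].strip())] = v
    return CalibrationTable(entries)


def write_calibration_table(cal: CalibrationTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tdataset_id\tvalue\n")
        for (pid, did), v in sorted(cal.entries.items()):
            fh.write(f"{pid}\t{did}\t{_fmt(v)}\n")


def read_dataset_meta(path: str | Path) -> list[DatasetMeta]:
    """Read dataset metadata TSV (targets ';'-joined in one cell)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    out = []
    for rec in df.itertuples(index=False):
        d = dict(zip(df.columns, rec))
        targets = frozenset(
            t for t in d["target_protein_ids"].split(";") if t.strip()
        )
        out.append(
            DatasetMeta(
                dataset_id=d["dataset_id"].strip(),
                target_protein_ids=targets,
                antibody_id=d["antibody_id"].strip(),
                control_kind=d["control_kind"].strip() or "none",
                replicate_group=d["replicate_group"].strip(),
                serial_position=d["serial_position"].strip() or "not_serial",
            )
        )
    ids = [m.dataset_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("dataset ids must be unique")
    return out


def write_dataset_meta(datasets: Sequence[DatasetMeta], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for m in datasets:
            fh.write(
                "\t".join(
                    [
                        m.dataset_id,
                        ";".join(sorted(m.target_protein_ids)),
                        m.antibody_id,
                        m.control_kind,
                        m.replicate_group,
                        m.serial_position,
                    ]
                )
                + "\n"
            )


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a numeric stage-output table with the shared float format."""
    df.to_csv(
        Path(path),
        sep="\t",
        float_format=FLOAT_FMT,
        index_label=index_label,
        na_rep="",
        lineterminator="\n",
    )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)
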