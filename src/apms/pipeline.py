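"""End-to-end orchestration: quant -> interactomics -> report.

``run_pipeline`` is a pure function of (inputs, config, seed): the same
inputs and configuration always produce byte-identical numeric tables.
Stage timings and every configuration parameter are echoed into
``pipeline_log.txt``; any stage error aborts the run with the stage
name.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import interactomics, quant, report
from .io_model import (
    PipelineConfig,
    read_calibration_table,
    read_dataset_meta,
    read_pv_table,
    write_table,
)

logger = logging.getLogger("apms")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    pv_table: str | Path,
    calibration: str | Path | None = None,
    dataset_meta: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Path]:
    """Run all stages on one PV table; returns the written table paths."""
    config.validate()
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)

    # -- startup: validate every input before touching the output directory
    inputs = [Path(pv_table)]
    if calibration is not None:
        inputs.append(Path(calibration))
    if dataset_meta is not None:
        inputs.append(Path(dataset_meta))
    missing = [str(p) for p in inputs if not p.exists()]
    if missing:
        raise PipelineError("startup", FileNotFoundError(", ".join(missing)))

    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline_log.txt"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    written: dict[str, Path] = {}
    try:
        for key, value in sorted(config.to_dict().items()):
            logger.info("config %s = %r", key, value)

        # ---------------- quant ----------------
        t0 = time.perf_counter()
        try:
            pv = read_pv_table(pv_table)
            qr = quant.protein_profiles(
                pv,
                k_min=config.k_min,
                k_cap=config.k_cap,
                fraction=config.fraction,
                min_shared=config.min_shared,
                outlier_r_cutoff=config.outlier_r_cutoff,
            )
            profiles = qr.profiles
            if calibration is not None:
                cal = read_calibration_table(calibration)
                abundance, _ = quant.calibrate_all(profiles, cal)
                # proteins without standards keep their relative profile
                abundance = abundance.where(abundance.notna(), profiles)
            else:
                abundance = profiles
            meta = read_dataset_meta(dataset_meta) if dataset_meta else None
            if meta is not None:
                normalized, ampar = quant.normalize_to_target(abundance, meta)
            else:
                normalized, ampar = abundance, quant.ampar_amount(abundance)
            write_table(profiles, out / "protein_profiles.tsv", "protein_id")
            write_table(abundance, out / "molecular_abundance.tsv", "protein_id")
            write_table(normalized, out / "normalized_abundance.tsv", "protein_id")
            write_table(
                ampar.to_frame().T, out / "ampar_amount.tsv", "quantity"
            )
            written.update(
                {
                    "protein_profiles": out / "protein_profiles.tsv",
                    "molecular_abundance": out / "molecular_abundance.tsv",
                    "normalized_abundance": out / "normalized_abundance.tsv",
                    "ampar_amount": out / "ampar_amount.tsv",
                }
            )
        except Exception as exc:
            logger.error("quant failed: %s", exc)
            raise PipelineError("quant", exc) from exc
        logger.info("stage quant finished in %.2f s", time.perf_counter() - t0)

        # ---------------- interactomics ----------------
        t0 = time.perf_counter()
        try:
            if meta is not None:
                _interactomics_stage(
                    config, normalized, abundance, meta, out, written
                )
            else:
                logger.info("no dataset metadata: interactomics stage skipped")
        except Exception as exc:
            logger.error("interactomics failed: %s", exc)
            raise PipelineError("interactomics", exc) from exc
        logger.info(
            "stage interactomics finished in %.2f s", time.perf_counter() - t0
        )

        # ---------------- report ----------------
        t0 = time.perf_counter()
        try:
            report.build_report(out, out / "report")
            written["report"] = out / "report" / "report.json"
        except Exception as exc:
            logger.error("report failed: %s", exc)
            raise PipelineError("report", exc) from exc
        logger.info("stage report finished in %.2f s", time.perf_counter() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return written


def _interactomics_stage(config, normalized, abundance, meta, out, written) -> None:
    by_kind: dict[str, list] = {}
    for m in meta:
        by_kind.setdefault(m.control_kind, []).append(m)
    ap_by_antibody: dict[str, list[str]] = {}
    for m in by_kind.get("none", []):
        if m.serial_position == "not_serial":
            ap_by_antibody.setdefault(m.antibody_id, []).append(m.dataset_id)

    comparisons = []
    rpv_frames = []
    for kind in ("igg", "depletion", "knockout"):
        controls = [m.dataset_id for m in by_kind.get(kind, [])]
        if not controls:
            continue
        for antibody, ap_ids in sorted(ap_by_antibody.items()):
            rpv = interactomics.compute_rpv(
                normalized, ap_ids, controls, config.imputation_factor
            )
            threshold = interactomics.estimate_threshold(
                rpv["rpv"], config.threshold_multiplier
            )
            name = f"{antibody}_vs_{kind}"
            comparisons.append(
                interactomics.Comparison(name, antibody, kind, rpv, threshold)
            )
            tagged = rpv.copy()
            tagged.insert(0, "comparison", name)
            tagged["threshold"] = threshold
            rpv_frames.append(tagged)
    if comparisons:
        write_table(pd.concat(rpv_frames), out / "rpv_table.tsv", "protein_id")
        calls = interactomics.call_specific(
            comparisons, n_antibody_min=config.n_antibody_min
        )
        write_table(calls, out / "specificity_calls.tsv", "protein_id")
        written["rpv_table"] = out / "rpv_table.tsv"
        written["specificity_calls"] = out / "specificity_calls.tsv"
    else:
        logger.info("no control datasets: specificity analysis skipped")

    firsts = [m.dataset_id for m in meta if m.serial_position == "first"]
    seconds = [m.dataset_id for m in meta if m.serial_position == "second"]
    if firsts and seconds:
        # serial APs are partitioned on a shared abundance scale, not on
        # per-step target-normalized values (the two steps have different
        # targets, which would break the F + (1 - F) = 1 conservation)
        ts = interactomics.twostep_partition(abundance, firsts, seconds)
        write_table(ts, out / "twostep_fractions.tsv", "protein_id")
        written["twostep_fractions"] = out / "twostep_fractions.tsv"
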