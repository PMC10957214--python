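"""Pipeline orchestration: simulate -> preprocess -> static FC -> dynamic FC.

Also hosts the small acquisition-parameter arithmetic (plane-wave count and
pulse repetition frequency of compound Doppler imaging).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    InvalidInputError,
    RoiSet,
    load_cohort,
    write_matrix,
    write_sidecar,
    write_table,
)
from .preprocess import ScrubConfig, scrub_report
from .staticfc import compare_conditions, correlation_matrix, edge_observations, mean_condition_matrix
from .dynfc import (
    animal_state_homogeneity,
    cofluctuation_series,
    compare_occurrence,
    concatenate_cohort,
    filter_outliers,
    kmeans_l1,
    occurrence_rates,
)

__all__ = [
    "AcqParams",
    "plane_wave_count",
    "pulse_repetition_frequency",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcqParams:
    """Plane-wave compounding parameters of the ultrafast Doppler sequence."""

    angle_min_deg: float = -10.0
    angle_max_deg: float = 10.0
    angle_step_deg: float = 2.0
    compound_frame_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.angle_step_deg <= 0:
            raise InvalidInputError("angle step must be positive")
        if self.angle_max_deg < self.angle_min_deg:
            raise InvalidInputError("angle_max must be >= angle_min")


def plane_wave_count(params: AcqParams) -> int:
    """Number of tilted plane waves in the inclusive angle sweep."""
    span = params.angle_max_deg - params.angle_min_deg
    steps = span / params.angle_step_deg
    if abs(steps - round(steps)) > 1e-9:
        raise InvalidInputError(
            f"angle span {span} is not divisible by step {params.angle_step_deg}"
        )
    return int(round(steps)) + 1


def pulse_repetition_frequency(params: AcqParams) -> float:
    """PRF in Hz: plane waves per compound frame times the frame rate."""
    return plane_wave_count(params) * params.compound_frame_rate_hz


@dataclass
class PipelineConfig:
    """One config drives all pipeline stages."""

    manifest: str = ""
    out_dir: str = "thermofc_out"
    scrub: ScrubConfig = field(default_factory=ScrubConfig)
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("15C", "25C")])
    k: int = 7
    restarts: int = 500
    outlier_z: float = 3.0
    fdr_q: float = 0.05
    seed: int = 0
    max_iter: int = 300

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, roi: RoiSet | None = None,
                 acquisitions=None) -> dict:
    """Run preprocess -> static FC -> dynamic FC over a cohort and write a report.

    ``acquisitions`` may be passed directly (in-memory cohort); otherwise
    the manifest is read and acquisition files are loaded from disk.  All
    numeric outputs are delimited text with a JSON sidecar recording the
    seed, config hash and package version.  Returns the report dict.
    """
    roi = roi or RoiSet()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "version": __version__}

    stage = "preprocess"
    try:
        if acquisitions is None:
            acquisitions = load_cohort(config.manifest, roi)
        cleaned, scrub_table = scrub_report(acquisitions, config.scrub)
        write_table(out / "scrub_report.csv", scrub_table)
        if not cleaned:
            raise InvalidInputError("all acquisitions were discarded by scrubbing")

        meta = pd.DataFrame({
            "acquisition_id": [c.source_id for c in cleaned],
            "animal_id": [c.animal_id for c in cleaned],
            "condition": [c.condition for c in cleaned],
        })

        stage = "staticfc"
        matrices = [correlation_matrix(c) for c in cleaned]
        obs = edge_observations(matrices, meta)
        static_results = {}
        for condition in sorted(meta["condition"].unique()):
            m = mean_condition_matrix(matrices, meta, condition)
            write_matrix(out / f"mean_correlation_{condition}.csv", m, roi.names)
        for pair in config.contrasts:
            avail = set(meta["condition"])
            if not set(pair) <= avail:
                logger.warning("contrast %s skipped: conditions not in cohort", pair)
                continue
            sig, delta, table = compare_conditions(obs, tuple(pair), roi, config.fdr_q)
            tag = f"{pair[0]}_vs_{pair[1]}"
            write_matrix(out / f"significance_{tag}.csv", sig.astype(int), roi.names)
            write_matrix(out / f"delta_z_{tag}.csv", delta, roi.names)
            write_table(out / f"edge_tests_{tag}.csv", table)
            static_results[tag] = {
                "n_significant_edges": int(sig[np.triu_indices(roi.n, 1)].sum()),
                "n_testable": int((table["status"] == "ok").sum()),
            }

        stage = "dynfc"
        cofl = concatenate_cohort([cofluctuation_series(c) for c in cleaned])
        filtered, keep = filter_outliers(cofl, config.outlier_z)
        model = kmeans_l1(filtered.values, config.k, restarts=config.restarts,
                          max_iter=config.max_iter, seed=config.seed)
        for rank, s in enumerate(model.state_order, start=1):
            from .core import devectorize_symmetric
            cm = devectorize_symmetric(model.centroids[s], roi.n, with_diagonal=True)
            write_matrix(out / f"state_{rank:02d}_centroid.csv", cm, roi.names)
        occ = occurrence_rates(model, filtered.frame_meta)
        write_table(out / "occurrence_rates.csv", occ)
        shares, chi2, chi2_p = animal_state_homogeneity(model, filtered.frame_meta) \
            if filtered.frame_meta["animal_id"].nunique() >= 2 else (None, np.nan, np.nan)
        occ_stats = compare_occurrence(occ, q=config.fdr_q)
        write_table(out / "occurrence_stats.csv", occ_stats)

        report = {
            "stages": ["preprocess", "staticfc", "dynfc"],
            "scrub": {
                "n_acquisitions": len(acquisitions),
                "n_kept": len(cleaned),
                "frames_raw": int(scrub_table["frames_raw"].sum()),
                "frames_kept": int(scrub_table["frames_kept"].sum()),
            },
            "static": static_results,
            "dynamic": {
                "frames_clustered": int(filtered.n_frames),
                "frames_outlier_removed": int((~keep).sum()),
                "k": config.k,
                "total_within_l1": model.total_within_l1,
                "occurrence_overall": {
                    int(s): float((model.labels == s).mean()) for s in range(config.k)
                },
                "homogeneity_chi2": chi2,
                "homogeneity_p": chi2_p,
                "n_states_flagged": int(
                    occ_stats.loc[occ_stats["kind"] == "omnibus", "significant"].sum()
                ),
            },
            **provenance,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        write_sidecar(out / "run_sidecar.json", **provenance)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
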