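"""End-to-end orchestration: raw peak lists to a machine-readable report.

One configured call runs the whole analysis — read (or ingest pre-aligned),
align, filter, normalise, log-transform, alpha/beta diversity, iterated
pair-balanced PERMANOVA, dispersion test, NMDS, mixed models and the
detectability beta regression — under a single master seed, and returns a
report whose every number is recomputable from inputs + config + seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity, bray_curtis, detectability_profile
from .ordination import DispersionResult, OrdinationResult, dispersion_test, nmds
from .peak_processing import (
    AlignedPeakMatrix,
    align_peaks,
    filter_substances,
    log_transform,
    normalize_relative,
    read_peak_lists,
)
from .permanova import DEFAULT_TERMS, IteratedPermanovaResult, iterated_permanova
from .regression import BetaRegFit, LmmFit, fit_alpha_lmm, fit_detectability_betareg

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("chemprofile")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults reproduce the analysis settings of the emulated study: 9,999
    permutations, 1,000 exclusion iterations, alpha = 0.05, percent-scale
    relative abundances log(X+1)-transformed before diversity analysis.
    """

    peak_paths: Sequence[str] = ()
    metadata_path: str = ""
    prealigned_path: str | None = None  # bypasses the alignment stage
    rt_tolerance: float = 0.05  # minutes
    normalization_scale: float = 100.0  # percent; 1.0 for proportions
    diversity_stage: str = "log_relative"  # or "relative"
    terms: Sequence[str] = DEFAULT_TERMS
    n_perm: int = 9999
    n_iterations: int = 1000
    alpha: float = 0.05
    include_interaction_lmm: bool = True
    nmds_k: int = 2
    nmds_restarts: int = 20
    betareg_degree: int = 2
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """All results of one pipeline run plus a config fingerprint."""

    summary: dict
    alpha_table: pd.DataFrame
    permanova: IteratedPermanovaResult
    dispersion: DispersionResult
    nmds: OrdinationResult
    lmm_shannon: LmmFit
    lmm_richness: LmmFit
    betareg: BetaRegFit
    config: RunConfig
    version: str = __version__

    def to_json_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="list")
            if isinstance(obj, pd.Series):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        perma = self.permanova
        return clean(
            {
                "version": self.version,
                "config": asdict(self.config),
                "summary": self.summary,
                "alpha_diversity": self.alpha_table,
                "iterated_permanova": {
                    "summary": perma.summary,
                    "pooled_p": perma.pooled_p,
                    "n_iterations": perma.n_iterations,
                    "n_perm": perma.n_perm,
                },
                "dispersion": {
                    "groups": self.dispersion.groups,
                    "group_mean_distances": self.dispersion.group_means,
                    "F": self.dispersion.f,
                    "P": self.dispersion.p,
                    "n_perm": self.dispersion.n_perm,
                },
                "nmds": {
                    "stress": self.nmds.stress,
                    "converged": self.nmds.converged,
                    "coordinates": self.nmds.to_frame(),
                },
                "lmm_shannon": self.lmm_shannon.to_frame(),
                "lmm_richness": self.lmm_richness.to_frame(),
                "betareg_detectability": {
                    "table": self.betareg.to_frame(),
                    "phi": self.betareg.phi,
                    "log_likelihood": self.betareg.log_likelihood,
                    "boundary_transformed": self.betareg.boundary_transformed,
                },
            }
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")
        self.alpha_table.to_csv(out / "alpha_diversity.csv", index=False)
        self.permanova.summary.to_csv(out / "permanova_summary.csv", index=False)
        self.nmds.to_frame().to_csv(out / "nmds_coordinates.csv")
        self.lmm_shannon.to_frame().to_csv(out / "lmm_shannon.csv", index=False)
        self.lmm_richness.to_frame().to_csv(out / "lmm_richness.csv", index=False)
        self.betareg.to_frame().to_csv(out / "betareg_detectability.csv", index=False)


def _summarise(matrix: AlignedPeakMatrix, meta: pd.DataFrame) -> dict:
    biol = meta[~meta["is_blank"]]
    per_sample = (matrix.values > 0).sum(axis=1)
    sex_counts = biol["sex"].value_counts().to_dict()
    return {
        "n_samples": int(matrix.n_samples),
        "n_samples_per_sex": {k: int(v) for k, v in sex_counts.items()},
        "n_substances": int(matrix.n_substances),
        "mean_substances_per_sample": float(per_sample.mean()),
        "sd_substances_per_sample": float(per_sample.std(ddof=1)),
        "n_substances_in_all_samples": int(((matrix.values > 0).all(axis=0)).sum()),
    }


def run_pipeline(
    config: RunConfig,
    peak_lists=None,
    metadata: pd.DataFrame | None = None,
    prealigned: AlignedPeakMatrix | None = None,
) -> RunReport:
    """Execute every stage of the analysis under one master seed.

    Inputs may be passed in memory (``peak_lists`` + ``metadata``, or
    ``prealigned`` + ``metadata``) or read from the locations in ``config``.
    Stochastic stages (iterated PERMANOVA, dispersion permutations, NMDS
    restarts) draw from named substreams of ``config.seed``, so reruns are
    bit-identical and stages can be rerun independently.
    """
    if metadata is None:
        log.info("stage=read files=%d", len(config.peak_paths))
        if config.prealigned_path:
            from .peak_processing import read_metadata

            prealigned = AlignedPeakMatrix.read(config.prealigned_path)
            metadata = read_metadata(config.metadata_path)
        else:
            peak_lists, metadata = read_peak_lists(config.peak_paths, config.metadata_path)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_iter, seed_disp, seed_nmds = (
        int(np.random.default_rng(s).integers(2**31)) for s in seeds
    )

    if prealigned is not None:
        aligned = prealigned
        log.info("stage=align skipped=prealigned n_substances=%d", aligned.n_substances)
    else:
        aligned = align_peaks(peak_lists, config.rt_tolerance)
        log.info("stage=align n_substances=%d", aligned.n_substances)
    filtered = filter_substances(aligned, metadata)
    log.info("stage=filter kept=%d of %d", filtered.n_substances, aligned.n_substances)
    relative = normalize_relative(filtered, config.normalization_scale)
    logged = log_transform(relative)
    div_matrix = logged if config.diversity_stage == "log_relative" else relative

    summary = _summarise(filtered, metadata)
    alpha_tab = alpha_diversity(div_matrix)
    log.info("stage=diversity mean_richness=%.1f", alpha_tab["richness"].mean())

    D = bray_curtis(div_matrix, accept_stages=(div_matrix.stage,))
    perma = iterated_permanova(
        D,
        metadata,
        terms=config.terms,
        n_iterations=config.n_iterations,
        n_perm=config.n_perm,
        seed=seed_iter,
    )
    log.info("stage=permanova pooled_p=%s", np.round(perma.pooled_p, 4))

    biol = metadata[~metadata["is_blank"]].set_index("sample_id").loc[list(D.sample_ids)]
    disp = dispersion_test(D, biol["sex"].to_numpy(), n_perm=config.n_perm, seed=seed_disp)
    log.info("stage=dispersion F=%.3f P=%.3f", disp.f, disp.p)

    ord_res = nmds(D, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=seed_nmds)
    log.info("stage=nmds stress=%.4f converged=%s", ord_res.stress, ord_res.converged)

    lmm_sh = fit_alpha_lmm(
        alpha_tab["shannon"].to_numpy(), metadata, config.include_interaction_lmm
    )
    lmm_ri = fit_alpha_lmm(
        alpha_tab["richness"].to_numpy(), metadata, config.include_interaction_lmm
    )
    log.info("stage=lmm shannon_sex=%.3f richness_sex=%.3f", lmm_sh.beta[1], lmm_ri.beta[1])

    betareg = fit_detectability_betareg(
        detectability_profile(filtered), degree=config.betareg_degree
    )
    log.info("stage=betareg quadratic=%.3f", betareg.beta[2] if len(betareg.beta) > 2 else np.nan)

    report = RunReport(
        summary=summary,
        alpha_table=alpha_tab,
        permanova=perma,
        dispersion=disp,
        nmds=ord_res,
        lmm_shannon=lmm_sh,
        lmm_richness=lmm_ri,
        betareg=betareg,
        config=config,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[chemprofile] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
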