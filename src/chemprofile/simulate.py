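"""Synthetic GC-MS peak-table datasets with the structure the analysis assumes.

The generator emulates a field study of preen-oil profiles: ~20 biological
samples (9 females, 11 males, with 4 breeding pairs contributing both
partners), 7 solvent-only blanks, and on the order of a hundred substances
with right-skewed abundances.  Each substance has a fixed true retention
time; observed retention times are jittered per sample.  Log abundances are
normal around a substance-specific level (itself drawn from a
between-substance distribution, which makes detection proportions vary from
rare to ubiquitous), plus a shared breeding-pair effect and, on a flagged
subset of substances, a multiplicative sex effect delta (delta = 0 is the
null).  Areas below a detection threshold are censored to zero — that is
what produces presence/absence structure and sample-to-sample variation in
richness.  Blank-borne contaminant substances and single-sample substances
are planted so the filtering rules have something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peak_processing import RawPeakList, filter_substances, log_transform, normalize_relative, align_peaks
from .permanova import DEFAULT_TERMS, iterated_permanova

__all__ = ["SimConfig", "SimDataset", "generate_dataset", "rejection_rate_experiment", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated field study: 9 females + 11 males sampled
    during incubation (days after laying 1-33), four complete breeding
    pairs, seven blanks, and enough shared substances that ~95 survive
    filtering with ~60-65 detected per sample.
    """

    n_females: int = 9
    n_males: int = 11
    n_complete_pairs: int = 4
    n_blanks: int = 7
    n_substances: int = 105  # shared substance pool (pre-filter)
    n_blank_contaminants: int = 5
    n_singleton_substances: int = 3
    base_log_abundance_mean: float = 10.0  # ln(area units)
    base_log_abundance_sd: float = 1.0  # within-substance, across samples
    substance_level_sd: float = 1.8  # between-substance spread of levels
    detection_threshold: float = 1e4  # area units
    sex_effect_size: float = 0.0  # delta, log-units; 0 = null
    sex_effect_fraction: float = 0.3  # fraction of substances carrying delta
    pair_effect_sd: float = 0.3  # log-units, shared by breeding partners
    rt_range: tuple[float, float] = (5.0, 30.0)  # minutes
    rt_min_spacing: float = 0.15  # minutes between true substance RTs
    rt_jitter_sd: float = 0.01  # minutes, per observed peak
    days_range: tuple[int, int] = (1, 33)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_females, self.n_males, self.n_complete_pairs, self.n_blanks,
            self.n_substances, self.n_blank_contaminants, self.n_singleton_substances,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_complete_pairs > min(self.n_females, self.n_males):
            raise ValueError("n_complete_pairs exceeds available females or males")
        if self.rt_jitter_sd >= self.rt_min_spacing / 4:
            raise ValueError("rt_jitter_sd must be < rt_min_spacing / 4 for alignability")
        n_total = self.n_substances + self.n_blank_contaminants + self.n_singleton_substances
        lo, hi = self.rt_range
        if hi - lo < n_total * self.rt_min_spacing:
            raise ValueError("rt_range too narrow for the requested substances and spacing")


@dataclass
class SimDataset:
    """Generated peak lists, metadata, and the generating truth."""

    peak_lists: list[RawPeakList]
    metadata: pd.DataFrame
    truth: dict = field(repr=False, default_factory=dict)
    config: SimConfig | None = None


def _spaced_rts(rng: np.random.Generator, n: int, lo: float, hi: float, gap: float) -> np.ndarray:
    """Sorted retention times uniform on [lo, hi] with a minimum spacing."""
    slack = (hi - lo) - (n - 1) * gap
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + gap * np.arange(n)


def generate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimDataset:
    """Draw one synthetic dataset; bit-reproducible from (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- samples and metadata ------------------------------------------------
    females = [f"F{i+1:02d}" for i in range(config.n_females)]
    males = [f"M{i+1:02d}" for i in range(config.n_males)]
    blanks = [f"BLK{i+1:02d}" for i in range(config.n_blanks)]
    pair_of = {}
    for p in range(config.n_complete_pairs):
        pair_of[females[p]] = f"P{p+1}"
        pair_of[males[p]] = f"P{p+1}"
    lo_d, hi_d = config.days_range
    days = {}
    for p in range(config.n_complete_pairs):  # partners share a nest, hence a laying day
        d = int(rng.integers(lo_d, hi_d + 1))
        days[females[p]] = d
        days[males[p]] = d
    for sid in females[config.n_complete_pairs:] + males[config.n_complete_pairs:]:
        days[sid] = int(rng.integers(lo_d, hi_d + 1))
    meta = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "sex": "female" if sid in females else "male",
                "pair_id": pair_of.get(sid),
                "days_after_laying": days[sid],
                "is_blank": False,
            }
            for sid in females + males
        ]
        + [
            {
                "sample_id": sid,
                "sex": "not-applicable",
                "pair_id": None,
                "days_after_laying": np.nan,
                "is_blank": True,
            }
            for sid in blanks
        ]
    )

    # --- substances ----------------------------------------------------------
    n_total = config.n_substances + config.n_blank_contaminants + config.n_singleton_substances
    true_rt = _spaced_rts(rng, n_total, *config.rt_range, config.rt_min_spacing)
    roles = np.array(
        ["shared"] * config.n_substances
        + ["contaminant"] * config.n_blank_contaminants
        + ["singleton"] * config.n_singleton_substances
    )
    rng.shuffle(roles)
    shared = np.where(roles == "shared")[0]
    contaminants = np.where(roles == "contaminant")[0]
    singletons = np.where(roles == "singleton")[0]

    level = np.full(n_total, np.nan)
    level[shared] = rng.normal(
        config.base_log_abundance_mean, config.substance_level_sd, size=len(shared)
    )
    sex_flag = np.zeros(n_total, dtype=bool)
    n_affected = int(round(config.sex_effect_fraction * len(shared)))
    sex_flag[rng.choice(shared, size=n_affected, replace=False)] = True

    pair_effect = {}
    for pid in sorted({v for v in pair_of.values()}):
        pair_effect[pid] = rng.normal(0.0, config.pair_effect_sd)
    sample_latent = {}
    for sid in females + males:
        pid = pair_of.get(sid)
        sample_latent[sid] = pair_effect[pid] if pid else rng.normal(0.0, config.pair_effect_sd)

    # --- biological peak lists ----------------------------------------------
    ln_thresh = np.log(config.detection_threshold)
    peak_lists: list[RawPeakList] = []
    singleton_host = {
        int(s): (females + males)[rng.integers(config.n_females + config.n_males)]
        for s in singletons
    }
    for sid in females + males:
        is_male = sid in males
        mu = (
            level[shared]
            + sample_latent[sid]
            + config.sex_effect_size * sex_flag[shared] * is_male
        )
        log_area = rng.normal(mu, config.base_log_abundance_sd)
        detected = log_area >= ln_thresh
        idx = shared[detected]
        areas = np.exp(log_area[detected])
        # planted singleton substances, forced above threshold
        extra = [s for s, host in singleton_host.items() if host == sid]
        if extra:
            idx = np.concatenate([idx, np.asarray(extra, dtype=int)])
            areas = np.concatenate(
                [areas, np.exp(rng.normal(ln_thresh + 1.0, 0.5, size=len(extra)))]
            )
        # carry-over contamination can also show up in biological runs
        hit = contaminants[rng.random(len(contaminants)) < 0.5]
        if len(hit):
            idx = np.concatenate([idx, hit])
            areas = np.concatenate(
                [areas, np.exp(rng.normal(ln_thresh + 0.5, 0.5, size=len(hit)))]
            )
        rt_obs = true_rt[idx] + rng.normal(0.0, config.rt_jitter_sd, size=len(idx))
        order = np.argsort(rt_obs)
        peak_lists.append(RawPeakList(sid, rt_obs[order], areas[order]))

    # --- blanks: contaminants only ------------------------------------------
    blank_presence = rng.random((config.n_blanks, len(contaminants))) < 0.7
    for j in range(len(contaminants)):  # every contaminant seen in >= 1 blank
        if config.n_blanks and not blank_presence[:, j].any():
            blank_presence[rng.integers(config.n_blanks), j] = True
    for b, sid in enumerate(blanks):
        idx = contaminants[blank_presence[b]]
        areas = np.exp(rng.normal(ln_thresh + 0.5, 0.5, size=len(idx)))
        rt_obs = true_rt[idx] + rng.normal(0.0, config.rt_jitter_sd, size=len(idx))
        order = np.argsort(rt_obs)
        peak_lists.append(RawPeakList(sid, rt_obs[order], areas[order]))

    truth = {
        "true_rt": true_rt,
        "roles": roles,
        "sex_effect_flag": sex_flag,
        "substance_level": level,
        "sample_latent": sample_latent,
        "pair_effect": pair_effect,
        "singleton_host": singleton_host,
    }
    return SimDataset(peak_lists=peak_lists, metadata=meta, truth=truth, config=config)


def write_dataset(dataset: SimDataset, out_dir: str | Path) -> None:
    """Write peak lists (one CSV per sample), metadata CSV, and truth JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pl in dataset.peak_lists:
        pd.DataFrame({"rt": pl.rt, "area": pl.area}).to_csv(out / f"{pl.sample_id}.csv", index=False)
    meta = dataset.metadata.copy()
    meta["is_blank"] = meta["is_blank"].astype(int)
    meta.to_csv(out / "metadata.csv", index=False)
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in dataset.truth.items()
        if k not in ("sample_latent", "pair_effect", "singleton_host")
    }
    truth["sample_latent"] = {k: float(v) for k, v in dataset.truth["sample_latent"].items()}
    truth["pair_effect"] = {k: float(v) for k, v in dataset.truth["pair_effect"].items()}
    truth["singleton_host"] = {str(k): v for k, v in dataset.truth["singleton_host"].items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def rejection_rate_experiment(
    config: SimConfig | None = None,
    n_datasets: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    n_iterations: int = 50,
    n_perm: int = 199,
    terms: Sequence[str] = DEFAULT_TERMS,
    rt_tolerance: float = 0.05,
    collect_pvalues: bool = False,
) -> pd.DataFrame:
    """Rejection rate of the pooled PERMANOVA P over simulated datasets.

    Runs the full pipeline (align -> filter -> normalise -> log -> iterated
    PERMANOVA) on ``n_datasets`` independent draws and reports, per design
    term, the fraction of pooled P-values below ``alpha`` with its binomial
    standard error.  Individual dataset failures are counted, not fatal.
    With ``collect_pvalues`` the frame of per-dataset pooled P-values is
    attached as ``result.attrs["pvalues"]``.
    """
    config = config or SimConfig()
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    pvals = []
    failures = 0
    for i, stream in enumerate(streams):
        child = np.random.default_rng(stream)
        try:
            ds = generate_dataset(config, seed=int(child.integers(2**31)))
            aligned = align_peaks(ds.peak_lists, rt_tolerance)
            mat = log_transform(normalize_relative(filter_substances(aligned, ds.metadata)))
            res = iterated_permanova(
                mat,
                ds.metadata,
                terms=terms,
                n_iterations=n_iterations,
                n_perm=n_perm,
                seed=int(child.integers(2**31)),
            )
            pvals.append(res.pooled_p)
        except Exception:  # noqa: BLE001 - experiment keeps going
            failures += 1
    P = np.asarray(pvals)
    rate = (P < alpha).mean(axis=0)
    n_ok = P.shape[0]
    out = pd.DataFrame(
        {
            "term": list(terms),
            "rejection_rate": rate,
            "se": np.sqrt(rate * (1 - rate) / n_ok),
            "n_datasets": n_ok,
            "n_failures": failures,
            "alpha": alpha,
        }
    )
    if collect_pvalues:
        out.attrs["pvalues"] = pd.DataFrame(P, columns=list(terms))
    return out
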