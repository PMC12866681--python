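"""End-to-end cohort analysis: QC → response tables → fits → cohort summary.

The pipeline consumes a trial log (or in-memory sessions), applies the
session reliability criterion per animal, tallies per-condition response
tables, fits the psychometric model per animal, and aggregates: across-animal
psychometric curve summaries (mean ± SEM of right-response percentage per
cue combination) and the cohort trading-ratio summary (median / quartiles /
range over identifiable fits).  All outputs are plain text and deterministic
— identical input and configuration produce byte-identical report bundles.

A parameter-recovery experiment (simulate a cohort with known generating
parameters, run the pipeline, compare recovered trading ratios against the
generating ones over replicates) validates the whole chain.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import UnidentifiableDesignError
from .io import read_trial_log
from .model import FitConfig, FitResult, fit_psychometric
from .schema import (
    DEFAULT_ILD_GRID,
    DEFAULT_ITD_GRID,
    QCResult,
    ResponseTable,
    Session,
    build_response_table,
    filter_sessions,
)
from .simulate import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnimalResult",
    "PipelineResult",
    "CohortSummary",
    "run_pipeline",
    "curve_summaries",
    "cohort_summary",
    "recovery_experiment",
    "RecoveryResult",
]


@dataclass(frozen=True)
class PipelineConfig:
    qc_threshold: float = 0.75
    qc_inclusive: bool = True
    itd_grid: tuple[float, ...] = DEFAULT_ITD_GRID
    ild_grid: tuple[float, ...] = DEFAULT_ILD_GRID
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class AnimalResult:
    animal_id: str
    n_sessions_included: int
    n_sessions_excluded: int
    table: ResponseTable | None
    fit: FitResult | None
    excluded_reason: str | None = None


@dataclass
class CohortSummary:
    """Cohort-level trading-ratio statistics over identifiable fits."""

    per_animal: pd.DataFrame
    median_titr: float
    min_titr: float
    max_titr: float
    q25_titr: float
    q75_titr: float
    n_animals: int
    excluded: tuple[str, ...]


@dataclass
class PipelineResult:
    qc: QCResult
    animals: dict[str, AnimalResult]
    curves: pd.DataFrame | None
    cohort: CohortSummary | None
    config: PipelineConfig

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write the report bundle; returns the created paths (sorted)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        created: list[Path] = []

        def _write(name: str, text: str) -> None:
            p = out / name
            p.write_text(text, encoding="utf-8")
            created.append(p)

        _write("sessions_qc.csv", self.qc.table.to_csv(index=False))
        long_frames = []
        for aid in sorted(self.animals):
            a = self.animals[aid]
            if a.table is not None:
                _write(f"heatmap_{aid}.csv", a.table.to_matrix().to_csv())
                long_frames.append(a.table.to_long_frame())
            if a.fit is not None:
                _write(f"fit_{aid}.txt", a.fit.to_text())
        if long_frames:
            _write(
                "response_counts.csv",
                pd.concat(long_frames, ignore_index=True).to_csv(index=False),
            )
        if self.curves is not None:
            _write("curves.csv", self.curves.to_csv(index=False))
        if self.cohort is not None:
            _write("cohort_per_animal.csv", self.cohort.per_animal.to_csv(index=False))
            c = self.cohort
            _write(
                "cohort_summary.txt",
                "\n".join(
                    [
                        f"n_animals={c.n_animals}",
                        f"median_titr_us_per_db={c.median_titr!r}",
                        f"min_titr_us_per_db={c.min_titr!r}",
                        f"max_titr_us_per_db={c.max_titr!r}",
                        f"q25_titr_us_per_db={c.q25_titr!r}",
                        f"q75_titr_us_per_db={c.q75_titr!r}",
                        "excluded_animals=" + ",".join(c.excluded),
                    ]
                )
                + "\n",
            )
        cfg = dataclasses.asdict(self.config)
        _write(
            "run_log.txt",
            f"cuetrade version {_pkg_version}\n"
            + "\n".join(f"{k}={cfg[k]!r}" for k in sorted(cfg))
            + "\n",
        )
        return sorted(created)


def curve_summaries(tables: Mapping[str, ResponseTable]) -> pd.DataFrame:
    """Across-animal psychometric curves: mean ± SEM right-response percentage.

    For every (ITD, ILD) cell the mean is taken over the animal-level right
    percentages of the animals that presented the cell at least once, and the
    SEM is the sample standard deviation divided by √(number of animals) —
    the unit of replication is the animal, not the trial.  With a single
    contributing animal the mean is returned and the SEM is NaN (undefined).
    """
    if not tables:
        raise ValueError("no response tables supplied")
    frames = [t.to_long_frame() for t in tables.values()]
    allcells = pd.concat(frames, ignore_index=True)
    allcells = allcells[allcells["n_total"] > 0].copy()
    allcells["pct_right"] = 100.0 * allcells["p_right"]

    def _agg(g: pd.DataFrame) -> pd.Series:
        vals = g["pct_right"].to_numpy()
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        return pd.Series(
            {"mean_pct_right": mean, "sem_pct_right": sem, "n_animals": len(vals)}
        )

    out = (
        allcells.groupby(["itd_us", "ild_db"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_animals"] = out["n_animals"].astype(int)
    return out


def cohort_summary(fits: Mapping[str, FitResult]) -> CohortSummary:
    """Median/range/quartiles of per-animal trading ratios.

    Animals whose fit is flagged non-identifiable are excluded from the
    statistics (with a log line) but still listed in the per-animal table.
    The median uses the midpoint convention for even counts (NumPy default).
    """
    rows = []
    titrs = []
    excluded = []
    for aid in sorted(fits):
        f = fits[aid]
        rows.append(
            {
                "animal_id": aid,
                "titr_us_per_db": f.titr_us_per_db,
                "alpha_ild": f.params.alpha_ild,
                "alpha_itd": f.params.alpha_itd,
                "beta": f.params.beta,
                "gamma": f.params.gamma,
                "delta": f.params.delta,
                "neg_log_lik": f.neg_log_lik,
                "n_trials": f.n_trials,
                "converged": f.converged,
                "identifiable": f.identifiable,
                "flags": ",".join(sorted(f.identifiability_flags)),
            }
        )
        if f.identifiable:
            titrs.append(f.titr_us_per_db)
        else:
            excluded.append(aid)
            logger.info(
                "animal %s excluded from cohort statistics (flags: %s)",
                aid,
                ",".join(sorted(f.identifiability_flags)),
            )
    if not titrs:
        raise ValueError("no identifiable fits; cohort summary undefined")
    arr = np.asarray(titrs, dtype=float)
    return CohortSummary(
        per_animal=pd.DataFrame(rows),
        median_titr=float(np.median(arr)),
        min_titr=float(arr.min()),
        max_titr=float(arr.max()),
        q25_titr=float(np.percentile(arr, 25)),
        q75_titr=float(np.percentile(arr, 75)),
        n_animals=len(titrs),
        excluded=tuple(excluded),
    )


def run_pipeline(
    source: str | Path | Sequence[Session],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run QC, tabulation, fitting and cohort aggregation on a trial log.

    ``source`` is a trial-log path or an in-memory session collection.  An
    animal whose every session fails QC (or whose design is unidentifiable)
    is reported as excluded and the pipeline completes for the rest.  If
    ``out_dir`` is given the text report bundle is written there.
    """
    cfg = config or PipelineConfig()
    sessions = (
        list(source)
        if not isinstance(source, (str, Path))
        else read_trial_log(source)
    )
    qc = filter_sessions(
        sessions, threshold=cfg.qc_threshold, inclusive=cfg.qc_inclusive
    )
    by_animal: dict[str, list[Session]] = {}
    for s in sessions:
        by_animal.setdefault(s.animal_id, [])
    for s in qc.included:
        by_animal[s.animal_id].append(s)
    n_excluded = {
        aid: sum(1 for s in qc.excluded if s.animal_id == aid) for aid in by_animal
    }

    animals: dict[str, AnimalResult] = {}
    for aid in sorted(by_animal):
        incl = by_animal[aid]
        if not incl:
            logger.warning("animal %s: all sessions failed QC; excluded", aid)
            animals[aid] = AnimalResult(
                aid, 0, n_excluded[aid], None, None, "all sessions failed QC"
            )
            continue
        table = build_response_table(
            incl, animal_id=aid, itd_grid=cfg.itd_grid, ild_grid=cfg.ild_grid
        )
        try:
            fit = fit_psychometric(table, cfg.fit)
        except UnidentifiableDesignError as exc:
            logger.warning("animal %s: fit stage failed: %s", aid, exc)
            animals[aid] = AnimalResult(
                aid, len(incl), n_excluded[aid], table, None, str(exc)
            )
            continue
        animals[aid] = AnimalResult(aid, len(incl), n_excluded[aid], table, fit)

    tables = {a.animal_id: a.table for a in animals.values() if a.table is not None}
    fits = {a.animal_id: a.fit for a in animals.values() if a.fit is not None}
    curves = curve_summaries(tables) if tables else None
    cohort = None
    if fits:
        try:
            cohort = cohort_summary(fits)
        except ValueError as exc:
            logger.warning("cohort summary unavailable: %s", exc)
    result = PipelineResult(
        qc=qc, animals=animals, curves=curves, cohort=cohort, config=cfg
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


@dataclass
class RecoveryResult:
    """Outcome of the parameter-recovery experiment."""

    table: pd.DataFrame  # replicate, animal_id, true/estimated TITR, rel_error
    cohort_medians: pd.DataFrame  # replicate, true/estimated cohort median

    def summary(self) -> dict[str, float]:
        ok = self.table[self.table["identifiable"]]
        rel = ok["rel_error"].to_numpy()
        return {
            "n_fits": int(len(self.table)),
            "n_identifiable": int(len(ok)),
            "median_abs_rel_error": float(np.median(np.abs(rel))),
            "mean_rel_error": float(np.mean(rel)),
            "rel_rmse": float(np.sqrt(np.mean(rel**2))),
            "frac_within_10pct": float(np.mean(np.abs(rel) <= 0.10)),
            "true_cohort_median": float(self.cohort_medians["true_median"].iloc[0]),
            "median_est_cohort_median": float(
                self.cohort_medians["est_median"].median()
            ),
        }


def recovery_experiment(
    spec: CohortSpec,
    n_replicates: int,
    seed: int,
    config: PipelineConfig | None = None,
) -> RecoveryResult:
    """Simulate → analyze → compare, ``n_replicates`` times.

    Each replicate simulates the cohort with a replicate-specific seed derived
    from ``seed``, runs the full pipeline (QC included) and records the
    generating versus recovered trading ratio per animal, plus the cohort
    medians.  Deterministic in (spec, seed).
    """
    cfg = config or PipelineConfig()
    true_titr = {
        o.animal_id: o.params.alpha_ild / o.params.alpha_itd for o in spec.observers
    }
    true_median = float(np.median(list(true_titr.values())))
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(n_replicates)
    ]
    rows = []
    med_rows = []
    for rep, rep_seed in enumerate(child_seeds):
        rep_spec = dataclasses.replace(spec, seed=rep_seed)
        sessions = simulate_cohort(rep_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_pipeline(sessions, cfg)
        for aid, a in result.animals.items():
            if a.fit is None:
                rows.append(
                    {
                        "replicate": rep,
                        "animal_id": aid,
                        "true_titr": true_titr[aid],
                        "est_titr": float("nan"),
                        "rel_error": float("nan"),
                        "identifiable": False,
                    }
                )
                continue
            est = a.fit.titr_us_per_db
            rows.append(
                {
                    "replicate": rep,
                    "animal_id": aid,
                    "true_titr": true_titr[aid],
                    "est_titr": est,
                    "rel_error": (est - true_titr[aid]) / true_titr[aid],
                    "identifiable": a.fit.identifiable,
                }
            )
        med_rows.append(
            {
                "replicate": rep,
                "true_median": true_median,
                "est_median": result.cohort.median_titr if result.cohort else float("nan"),
            }
        )
    return RecoveryResult(
        table=pd.DataFrame(rows), cohort_medians=pd.DataFrame(med_rows)
    )
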