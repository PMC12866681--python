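"""The additive cumulative-Gaussian-with-lapse lateralization model.

The probability that the observer reports "right" for a stimulus with
interaural time difference ``ITD`` (µs) and level difference ``ILD`` (dB) is

    p_R = Φ(α_ILD·ILD + α_ITD·ITD + β)·(1 − γ) + γ/2 + δ

where Φ is the standard normal CDF, α_ILD (1/dB) and α_ITD (1/µs) are the
cue sensitivities, β is an ear-bias offset on the probit axis, γ ∈ [0, 1) is
the lapse rate (fraction of stimulus-independent responses) and δ is a spout
bias applied on lapsed trials.  The constraint |δ| ≤ γ/2 keeps p_R inside
[0, 1] for every stimulus.

The time–intensity trading ratio (TITR) is the ITD that offsets a 1 dB ILD of
opposite direction, obtained from α_ILD·1 − α_ITD·TITR = 0:

    TITR = α_ILD / α_ITD     (units (1/dB)/(1/µs) = µs/dB)

Parameters are estimated by maximum likelihood on the per-cell binomial
sufficient statistics of a :class:`ResponseTable`, with deterministic
multi-start bounded quasi-Newton optimization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import ndtr, ndtri

from .errors import UndefinedTITRError, UnidentifiableDesignError
from .schema import ResponseTable, StimulusCondition

__all__ = [
    "PsychometricParams",
    "FitConfig",
    "FitResult",
    "predict_p_right",
    "neg_log_likelihood",
    "fit_psychometric",
    "compute_titr",
    "cancellation_itd",
    "solve_cancellation_itd",
    "residual_diagnostics",
]

#: Floor/ceiling applied to predicted probabilities inside the likelihood.
LIKELIHOOD_EPS = 1e-12

# Box bounds used during fitting.  The α and β caps handle separation
# (all-one-side data would otherwise push them to infinity); γ is kept off 1
# where the model degenerates to a pure guesser; δ is parameterized as the
# fraction δ/(γ/2) ∈ [-1, 1] so the |δ| ≤ γ/2 constraint is a box.
FIT_BOUNDS: tuple[tuple[float, float], ...] = (
    (-5.0, 5.0),  # alpha_ild, 1/dB
    (-0.5, 0.5),  # alpha_itd, 1/µs
    (-10.0, 10.0),  # beta
    (0.0, 0.99),  # gamma
    (-1.0, 1.0),  # delta as a fraction of γ/2
)


@dataclass(frozen=True)
class PsychometricParams:
    """The five model parameters; see the module docstring for the formula."""

    alpha_ild: float  # ILD sensitivity, 1/dB
    alpha_itd: float  # ITD sensitivity, 1/µs
    beta: float = 0.0  # ear bias (probit offset)
    gamma: float = 0.0  # lapse rate, in [0, 1)
    delta: float = 0.0  # spout bias, |delta| <= gamma / 2

    def __post_init__(self) -> None:
        vals = (self.alpha_ild, self.alpha_itd, self.beta, self.gamma, self.delta)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {vals}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if abs(self.delta) > self.gamma / 2 + 1e-12:
            raise ValueError(
                f"|delta|={abs(self.delta)} exceeds gamma/2={self.gamma / 2}; "
                "predicted probabilities would leave [0, 1]"
            )

    @property
    def delta_frac(self) -> float:
        """δ expressed as a fraction of its admissible range γ/2."""
        return 0.0 if self.gamma == 0 else self.delta / (self.gamma / 2)


def _p_right(
    params: PsychometricParams, itd_us: np.ndarray | float, ild_db: np.ndarray | float
) -> np.ndarray | float:
    """Vectorized model evaluation (no clamping: the invariants bound it)."""
    eta = params.alpha_ild * np.asarray(ild_db) + params.alpha_itd * np.asarray(
        itd_us
    ) + params.beta
    return ndtr(eta) * (1.0 - params.gamma) + params.gamma / 2.0 + params.delta


def predict_p_right(
    params: PsychometricParams, condition: StimulusCondition
) -> float:
    """Probability of a "right" response for one stimulus condition."""
    return float(_p_right(params, condition.itd_us, condition.ild_db))


def neg_log_likelihood(
    params: PsychometricParams,
    table: ResponseTable,
    eps: float = LIKELIHOOD_EPS,
) -> float:
    """Negative binomial log-likelihood of a response table.

    Uses the per-cell sufficient statistics
    ``-Σ [k·ln p + (n−k)·ln(1−p)]`` (binomial coefficients dropped: they are
    constant in the parameters, so the value is ≥ 0 and the argmin is the
    MLE).  Predicted probabilities are clipped to ``[eps, 1−eps]``; if the
    clip is active on a cell whose counts contradict the saturated
    probability, a warning is emitted and the value stays large but finite.
    """
    itd, ild, k, n = table.arrays()
    if itd.size == 0:
        raise ValueError("response table has no presented cells")
    p = np.asarray(_p_right(params, itd, ild), dtype=float)
    clipped_hi = (p > 1 - eps) & (k < n)
    clipped_lo = (p < eps) & (k > 0)
    if clipped_hi.any() or clipped_lo.any():
        warnings.warn(
            "predicted probability hit the epsilon guard on a cell with "
            "contradicting responses; likelihood is floored",
            RuntimeWarning,
            stacklevel=2,
        )
    p = np.clip(p, eps, 1 - eps)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def compute_titr(params: PsychometricParams) -> float:
    """Time–intensity trading ratio α_ILD / α_ITD in µs/dB.

    Negative values (discordant fitted cue directions) are returned as-is;
    the fitting layer flags them.  α_ITD = 0 has no defined ratio.
    """
    if params.alpha_itd == 0:
        raise UndefinedTITRError(
            "TITR undefined: alpha_itd is zero (ITD-blind observer)"
        )
    return params.alpha_ild / params.alpha_itd


def cancellation_itd(titr_us_per_db: float, ild_db: float) -> float:
    """ITD magnitude (µs) that offsets an ILD of ``ild_db`` dB.

    The canceling ITD points in the direction opposite to the ILD; this
    returns its magnitude ``titr · |ild|``.
    """
    if not math.isfinite(titr_us_per_db):
        raise ValueError("trading ratio must be finite")
    return titr_us_per_db * abs(ild_db)


def solve_cancellation_itd(
    params: PsychometricParams, ild_db: float, itd_limit_us: float = 1000.0
) -> float:
    """Numerically solve for the signed ITD that cancels ``ild_db``.

    Finds the root of ``p_right(ITD, ild) − p_right(0, 0)``, i.e. the ITD
    bringing the percept back to where the neutral stimulus sits.  With zero
    biases this equals ``−sign(ild)·TITR·|ild|`` and provides an independent
    cross-check of :func:`cancellation_itd`.
    """
    if params.alpha_itd == 0:
        raise UndefinedTITRError("no ITD can cancel an ILD when alpha_itd is 0")
    target = float(_p_right(params, 0.0, 0.0))

    def f(itd: float) -> float:
        return float(_p_right(params, itd, ild_db)) - target

    if ild_db == 0:
        return 0.0
    lo, hi = -itd_limit_us, itd_limit_us
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"no canceling ITD within ±{itd_limit_us} µs for ILD {ild_db} dB"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-14))


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_psychometric`."""

    n_starts: int = 16
    bounds: tuple[tuple[float, float], ...] = FIT_BOUNDS
    ftol: float = 1e-12
    gtol: float = 1e-8
    maxiter: int = 500
    eps: float = LIKELIHOOD_EPS
    #: Minimum log-likelihood gain of the cue model over a stimulus-blind
    #: constant-probability model; below this the TITR is flagged
    #: unidentifiable (the data carry no usable cue signal).
    min_signal_loglik_gain: float = 3.0


@dataclass
class FitResult:
    """Maximum-likelihood fit of one response table."""

    params: PsychometricParams
    neg_log_lik: float
    titr_us_per_db: float
    converged: bool
    n_trials: int
    identifiability_flags: frozenset[str]
    residuals: dict[tuple[float, float], float]

    @property
    def identifiable(self) -> bool:
        return not self.identifiability_flags & {
            "separation",
            "separation_alpha_ild",
            "separation_alpha_itd",
            "titr_unidentifiable",
            "titr_undefined",
        }

    def to_text(self) -> str:
        """Serialize to the key=value report consumed by the pipeline."""
        p = self.params
        lines = [
            f"alpha_ild={float(p.alpha_ild)!r}",
            f"alpha_itd={float(p.alpha_itd)!r}",
            f"beta={float(p.beta)!r}",
            f"gamma={float(p.gamma)!r}",
            f"delta={float(p.delta)!r}",
            f"neg_log_lik={self.neg_log_lik!r}",
            f"titr_us_per_db={self.titr_us_per_db!r}",
            f"converged={str(self.converged).lower()}",
            f"n_trials={self.n_trials}",
            "identifiability_flags=" + ",".join(sorted(self.identifiability_flags)),
        ]
        for (itd, ild), r in sorted(self.residuals.items()):
            lines.append(f"residual[{itd:g},{ild:g}]={r!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FitResult":
        kv: dict[str, str] = {}
        residuals: dict[tuple[float, float], float] = {}
        for line in text.strip().splitlines():
            key, _, value = line.partition("=")
            if key.startswith("residual["):
                cell = key[len("residual[") : -1]
                itd_s, ild_s = cell.split(",")
                residuals[(float(itd_s), float(ild_s))] = float(value)
            else:
                kv[key] = value
        params = PsychometricParams(
            alpha_ild=float(kv["alpha_ild"]),
            alpha_itd=float(kv["alpha_itd"]),
            beta=float(kv["beta"]),
            gamma=float(kv["gamma"]),
            delta=float(kv["delta"]),
        )
        flags = frozenset(
            f for f in kv["identifiability_flags"].split(",") if f
        )
        return cls(
            params=params,
            neg_log_lik=float(kv["neg_log_lik"]),
            titr_us_per_db=float(kv["titr_us_per_db"]),
            converged=kv["converged"] == "true",
            n_trials=int(kv["n_trials"]),
            identifiability_flags=flags,
            residuals=residuals,
        )


def _nll_vec(
    x: np.ndarray,
    itd: np.ndarray,
    ild: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    eps: float,
) -> float:
    a_ild, a_itd, beta, gamma, dfrac = x
    delta = 0.5 * gamma * dfrac
    p = ndtr(a_ild * ild + a_itd * itd + beta) * (1 - gamma) + gamma / 2 + delta
    p = np.clip(p, eps, 1 - eps)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def _probit_warm_start(
    itd: np.ndarray, ild: np.ndarray, k: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Weighted least squares on probit-transformed cell frequencies."""
    p_hat = np.clip((k + 0.5) / (n + 1.0), 0.01, 0.99)
    z = ndtri(p_hat)
    design = np.column_stack([ild, itd, np.ones_like(ild)])
    w = np.sqrt(n)
    coef, *_ = np.linalg.lstsq(design * w[:, None], z * w, rcond=None)
    return np.array([coef[0], coef[1], coef[2], 0.05, 0.0])


# Deterministic lattice of optimization starts (α_ILD, α_ITD, β, γ, δ-frac);
# covers both cue-sign quadrants, weak/strong sensitivity and a high-lapse
# regime so separation and guessing data sets still land in the right basin.
_START_LATTICE: tuple[tuple[float, float, float, float, float], ...] = (
    (0.2, 0.02, 0.0, 0.05, 0.0),
    (-0.2, 0.02, 0.0, 0.05, 0.0),
    (0.2, -0.02, 0.0, 0.05, 0.0),
    (-0.2, -0.02, 0.0, 0.05, 0.0),
    (0.2, 0.02, 0.0, 0.3, 0.0),
    (-0.2, 0.02, 0.0, 0.3, 0.0),
    (0.2, -0.02, 0.0, 0.3, 0.0),
    (-0.2, -0.02, 0.0, 0.3, 0.0),
    (0.05, 0.005, 0.0, 0.1, 0.0),
    (-0.05, -0.005, 0.0, 0.1, 0.0),
    (0.5, 0.05, 0.0, 0.1, 0.0),
    (1.0, 0.1, 0.0, 0.02, 0.0),
    (0.0, 0.0, 0.5, 0.1, 0.0),
    (0.0, 0.0, -0.5, 0.1, 0.0),
    (0.0, 0.0, 0.0, 0.8, 0.0),
)


def fit_psychometric(
    table: ResponseTable, config: FitConfig | None = None
) -> FitResult:
    """Fit the five-parameter model to a response table by maximum likelihood.

    Runs ``config.n_starts`` deterministic bounded L-BFGS-B optimizations (a
    probit-regression warm start plus a fixed lattice) in the box-constrained
    parameterization (α_ILD, α_ITD, β, γ, δ/(γ/2)) and keeps the best.  The
    design must present at least two distinct ITD and two distinct ILD levels,
    otherwise the corresponding sensitivity is structurally unidentifiable and
    :class:`UnidentifiableDesignError` is raised.

    Separation (responses perfectly predicted, driving a sensitivity to its
    bound) and absence of cue signal (the cue model beats a stimulus-blind
    constant model by less than ``min_signal_loglik_gain`` log-likelihood
    units) do not raise: the result is returned with identifiability flags.
    """
    cfg = config or FitConfig()
    itd, ild, k, n = table.arrays()
    if itd.size == 0:
        raise ValueError("response table has no presented cells")
    if np.unique(ild).size < 2:
        raise UnidentifiableDesignError(
            "design presents a single ILD level; alpha_ild is unidentifiable"
        )
    if np.unique(itd).size < 2:
        raise UnidentifiableDesignError(
            "design presents a single ITD level; alpha_itd is unidentifiable"
        )

    starts = [_probit_warm_start(itd, ild, k, n)]
    starts += [np.array(s) for s in _START_LATTICE]
    starts = starts[: cfg.n_starts]
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])

    best = None
    for x0 in starts:
        res = minimize(
            _nll_vec,
            np.clip(x0, lo, hi),
            args=(itd, ild, k, n, cfg.eps),
            method="L-BFGS-B",
            bounds=cfg.bounds,
            options={"ftol": cfg.ftol, "gtol": cfg.gtol, "maxiter": cfg.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    a_ild, a_itd, beta, gamma, dfrac = (float(v) for v in best.x)
    delta = 0.5 * gamma * dfrac
    params = PsychometricParams(a_ild, a_itd, beta, gamma, delta)

    flags: set[str] = set()
    span = hi - lo
    if np.all(k == n) or np.all(k == 0):
        flags.add("separation")  # responses all on one side
    if min(a_ild - lo[0], hi[0] - a_ild) < 1e-6 * span[0]:
        flags.add("separation_alpha_ild")
    if min(a_itd - lo[1], hi[1] - a_itd) < 1e-6 * span[1]:
        flags.add("separation_alpha_itd")
    if hi[3] - gamma < 1e-6:
        flags.add("gamma_at_bound")

    # Likelihood-ratio style check against the best stimulus-blind model:
    # if the cues explain (almost) nothing, the sensitivity ratio is noise.
    p_const = np.clip(k.sum() / n.sum(), cfg.eps, 1 - cfg.eps)
    nll_const = float(-(k.sum() * np.log(p_const) + (n - k).sum() * np.log1p(-p_const)))
    if nll_const - best.fun < cfg.min_signal_loglik_gain:
        flags.add("titr_unidentifiable")

    if a_itd == 0:
        flags.add("titr_undefined")
        titr = float("nan")
    else:
        titr = compute_titr(params)
        if titr < 0:
            flags.add("negative_titr")

    p_fit = np.asarray(_p_right(params, itd, ild))
    residuals = {
        (float(t), float(l)): float(kk / nn - pp)
        for t, l, kk, nn, pp in zip(itd, ild, k, n, p_fit)
    }

    return FitResult(
        params=params,
        neg_log_lik=float(best.fun),
        titr_us_per_db=titr,
        converged=bool(best.success),
        n_trials=int(n.sum()),
        identifiability_flags=frozenset(flags),
        residuals=residuals,
    )


def residual_diagnostics(
    fit: FitResult, table: ResponseTable
) -> tuple[dict[tuple[float, float], float], dict[str, object]]:
    """Recompute per-cell residuals (observed − predicted right fraction).

    Returns the residual mapping plus a summary: the maximum absolute
    residual, the signed mean, and a sign-pattern flag that is set when any
    full grid row or column (≥ 3 presented cells) has residuals of a single
    strict sign — the kind of recurring structure that would indicate the
    additive model misses an interaction.
    """
    itd, ild, k, n = table.arrays()
    if set(zip(itd, ild)) != set(fit.residuals):
        raise ValueError("fit was produced on a different grid than this table")
    p = np.asarray(_p_right(fit.params, itd, ild))
    res = k / n - p
    residuals = {
        (float(t), float(l)): float(r) for t, l, r in zip(itd, ild, res)
    }
    pattern = False
    for axis_vals, other in ((table.itd_grid, 1), (table.ild_grid, 0)):
        for v in axis_vals:
            line = [
                r
                for (cell_itd, cell_ild), r in residuals.items()
                if (cell_itd, cell_ild)[1 - other] == v
            ]
            if len(line) >= 3 and (all(r > 0 for r in line) or all(r < 0 for r in line)):
                pattern = True
    summary = {
        "max_abs_residual": float(np.max(np.abs(res))),
        "mean_residual": float(np.mean(res)),
        "n_cells": int(res.size),
        "sign_pattern": pattern,
    }
    return residuals, summary
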