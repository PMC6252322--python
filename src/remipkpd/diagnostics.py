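"""Goodness-of-fit and simulation-based model evaluation.

Provides the standard pharmacometric diagnostics: population (PRED) and
individual (IPRED) predictions against observations, conditionally
weighted residuals (CWRES) from a first-order linearisation of the model
around each subject's empirical Bayes etas, and (prediction-corrected)
visual predictive checks built by re-simulating the fitted model under
the observed design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .nlme import FitResult, _ProfileEngine
from .pd_moaas import sample_scores
from .trial_data import LLOQ, ObservationTable, ValidationError

__all__ = ["GOFTable", "VPCResult", "gof", "vpc", "plot_gof", "plot_vpc"]


@dataclass
class GOFTable:
    """Per-observation goodness-of-fit quantities (continuous endpoints)."""

    frame: pd.DataFrame  # columns: subject_id, time, observed, pred, ipred, cwres

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class VPCResult:
    """Visual predictive check summary.

    For continuous endpoints: observed 5/50/95 percentiles per time bin and
    the 95% CI of each percentile across simulated replicates.  For MOAA/S:
    observed per-category frequencies and their simulated CIs.
    """

    bins: np.ndarray  # bin centres (nominal times)
    observed: dict  # percentile (or category) -> (nbins,) observed values
    simulated_ci: dict  # key -> (2, nbins) lower/upper CI across replicates
    prediction_corrected: bool = False
    n_reps: int = 0
    endpoint: str = "continuous"

    def coverage(self, key=50) -> float:
        """Fraction of bins where the observed statistic is inside its CI."""
        obs = self.observed[key]
        lo, hi = self.simulated_ci[key]
        usable = np.isfinite(obs) & np.isfinite(lo) & np.isfinite(hi)
        ok = (obs[usable] >= lo[usable]) & (obs[usable] <= hi[usable])
        return float(np.mean(ok))


def _fit_pieces(fit: FitResult):
    ctx = fit._context
    if not ctx or "subjects" not in ctx:
        raise ValidationError("fit carries no data context")
    adapter = ctx["adapter"]
    fixed, omega, sigma = ctx["fixed"], ctx["omega"], ctx["sigma"]
    eta_names = [n for n in adapter.eta_candidates if omega.get(n, 0.0) > 0]
    if fit.model == "moaas" and omega.get("eta_logit", 0.0) > 0:
        eta_names = eta_names + ["eta_logit"]
    subjects = ctx["subjects"]
    engines = [_ProfileEngine(s.regimen, s.times) for s in subjects]
    return adapter, subjects, engines, fixed, omega, sigma, eta_names


def gof(table: ObservationTable, fit: FitResult) -> GOFTable:
    """PRED/IPRED and CWRES for a continuous-endpoint fit.

    PRED is the typical-subject prediction (eta = 0), IPRED the prediction
    at the empirical Bayes etas.  CWRES follows the FOCE-linearised
    definition: the model is linearised in eta around the EBE, giving the
    marginal covariance G Omega G' + R, and the population residual
    y - (F(eta_hat) - G eta_hat) is whitened with its Cholesky factor.
    """
    if fit.model == "moaas":
        raise ValidationError("GOF residuals are defined for continuous endpoints")
    adapter, subjects, engines, fixed, omega, sigma, eta_names = _fit_pieces(fit)
    if not fit.ebes:
        raise ValidationError("fit has no empirical Bayes estimates")
    d = len(eta_names)
    rows = []
    for subj, engine in zip(subjects, engines):
        ctx = (subj, engine)
        eta_hat = np.array(
            [fit.ebes[subj.subject_id].get(n, 0.0) for n in eta_names]
        )
        pred = adapter.predictions(ctx, fixed, np.zeros(d), eta_names, sigma)
        ipred = adapter.predictions(ctx, fixed, eta_hat, eta_names, sigma)
        nt = len(subj.times)
        if d > 0:
            h = 1e-4
            pts = [eta_hat]
            for j in range(d):
                e = np.zeros(d)
                e[j] = h
                pts += [eta_hat + e, eta_hat - e]
            preds = adapter._pred(ctx, fixed, np.array(pts), eta_names)
            g = np.stack(
                [(preds[1 + 2 * j] - preds[2 + 2 * j]) / (2 * h) for j in range(d)],
                axis=1,
            )  # (nt, d)
            omega_mat = np.diag([omega[n] ** 2 for n in eta_names])
        else:
            g = np.zeros((nt, 0))
            omega_mat = np.zeros((0, 0))
        f_lin = preds[0] if d > 0 else ipred
        if fit.model == "pk" or getattr(adapter, "residual_model", "") != "additive":
            res_var = (sigma * np.maximum(np.abs(f_lin), 1e-8)) ** 2
        else:
            res_var = np.full(nt, sigma**2)
        cov = g @ omega_mat @ g.T + np.diag(res_var)
        resid = subj.y - (f_lin - g @ eta_hat)
        try:
            chol = np.linalg.cholesky(cov)
            cwres = np.linalg.solve(chol, resid)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            cwres = resid / np.sqrt(np.diag(cov))
        for t, y, pr, ipr, cw in zip(subj.times, subj.y, pred, ipred, cwres):
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "time": t,
                    "observed": y,
                    "pred": pr,
                    "ipred": ipr,
                    "cwres": cw,
                }
            )
    return GOFTable(pd.DataFrame(rows))


def _simulate_subject(adapter, ctx, fixed, omega, sigma, eta_names, rng, endpoint):
    d = len(eta_names)
    eta = np.array([rng.normal(0.0, omega[n]) for n in eta_names]) if d else np.zeros(0)
    if endpoint == "moaas":
        cum = adapter._probs(ctx, fixed, np.atleast_2d(eta), eta_names)[0]
        probs = np.diff(cum, axis=-1, prepend=0.0)
        return sample_scores(np.clip(probs, 0.0, 1.0), rng).astype(float)
    pred = adapter.predictions(ctx, fixed, eta, eta_names, sigma)
    return adapter.simulate_obs(pred, sigma, rng)


def vpc(
    table: ObservationTable,
    fit: FitResult,
    n_reps: int = 500,
    bins: Sequence[float] | None = None,
    prediction_corrected: bool = False,
    rng_seed=None,
    percentiles: tuple = (5.0, 50.0, 95.0),
    ci: float = 95.0,
) -> VPCResult:
    """Visual predictive check by re-simulation under the observed design.

    Observations are grouped in time bins (default: the distinct nominal
    observation times); per bin the observed percentiles are compared with
    the ``ci``% interval of the same percentile across ``n_reps`` simulated
    replicate datasets.  With ``prediction_corrected`` both observations
    and simulations are scaled by bin-median PRED / subject-time PRED
    before binning.  For MOAA/S, per-category observed frequencies are
    compared with their simulated intervals.
    """
    adapter, subjects, engines, fixed, omega, sigma, eta_names = _fit_pieces(fit)
    rng = np.random.default_rng(rng_seed)
    endpoint = "moaas" if fit.model == "moaas" else "continuous"

    times_all = np.concatenate([s.times for s in subjects])
    y_all = np.concatenate([s.y for s in subjects])
    if bins is None:
        bins = np.unique(times_all)
    bins = np.asarray(bins, dtype=float)
    # nearest-bin assignment
    bin_idx = np.argmin(np.abs(times_all[:, None] - bins[None, :]), axis=1)
    occupied = np.unique(bin_idx)
    if len(occupied) < len(bins):
        warnings.warn("empty VPC bins dropped")
        bins = bins[occupied]
        bin_idx = np.argmin(np.abs(times_all[:, None] - bins[None, :]), axis=1)

    pc = np.ones_like(y_all)
    if prediction_corrected and endpoint == "continuous":
        d = len(eta_names)
        pred_all = np.concatenate(
            [
                adapter.predictions((s, e), fixed, np.zeros(d), eta_names, sigma)
                for s, e in zip(subjects, engines)
            ]
        )
        pred_all = np.maximum(np.abs(pred_all), 1e-8)
        bin_median_pred = np.array(
            [np.median(pred_all[bin_idx == b]) for b in range(len(bins))]
        )
        pc = bin_median_pred[bin_idx] / pred_all

    nbins = len(bins)
    # concentration data are left-censored at the assay LLOQ: observed
    # records below it were excluded, so simulated replicates must be
    # censored the same way before computing percentiles
    censor = LLOQ if fit.model == "pk" else None

    def bin_stats(values: np.ndarray, usable: np.ndarray) -> dict:
        out = {}
        if endpoint == "moaas":
            for k in range(6):
                out[k] = np.array(
                    [np.mean(values[(bin_idx == b) & usable] == k) for b in range(nbins)]
                )
        else:
            for p in percentiles:
                out[p] = np.array(
                    [
                        np.percentile(values[(bin_idx == b) & usable], p)
                        if ((bin_idx == b) & usable).any()
                        else np.nan
                        for b in range(nbins)
                    ]
                )
        return out

    observed = bin_stats(y_all * pc, np.ones_like(y_all, dtype=bool))

    sim_stats: dict = {k: [] for k in observed}
    for _ in range(n_reps):
        sim_all = np.concatenate(
            [
                _simulate_subject(
                    adapter, (s, e), fixed, omega, sigma, eta_names, rng, endpoint
                )
                for s, e in zip(subjects, engines)
            ]
        )
        usable = sim_all >= censor if censor is not None else np.ones_like(
            sim_all, dtype=bool
        )
        stats = bin_stats(sim_all * pc, usable)
        for k, v in stats.items():
            sim_stats[k].append(v)

    alpha = (100.0 - ci) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        simulated_ci = {
            k: np.nanpercentile(np.array(v), [alpha, 100.0 - alpha], axis=0)
            for k, v in sim_stats.items()
        }
    return VPCResult(
        bins=bins,
        observed=observed,
        simulated_ci=simulated_ci,
        prediction_corrected=prediction_corrected,
        n_reps=n_reps,
        endpoint=endpoint,
    )


def plot_gof(gof_table: GOFTable, path) -> None:
    """Four-panel GOF figure: DV vs PRED/IPRED, CWRES vs PRED and time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = gof_table.frame
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, xcol in zip(axes[0], ["pred", "ipred"]):
        ax.plot(df[xcol], df["observed"], "o", ms=3, alpha=0.5)
        lim = [0, max(df[xcol].max(), df["observed"].max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(xcol.upper())
        ax.set_ylabel("observed")
    for ax, xcol in zip(axes[1], ["pred", "time"]):
        ax.plot(df[xcol], df["cwres"], "o", ms=3, alpha=0.5)
        ax.axhline(0, color="k", ls="--", lw=1)
        ax.set_xlabel(xcol.upper())
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_vpc(result: VPCResult, path) -> None:
    """Percentile-band VPC figure (continuous) or category-frequency bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for k in result.observed:
        lo, hi = result.simulated_ci[k]
        ax.fill_between(result.bins, lo, hi, alpha=0.25)
        ax.plot(result.bins, result.observed[k], "-o", ms=3, label=str(k))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("frequency" if result.endpoint == "moaas" else "value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
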