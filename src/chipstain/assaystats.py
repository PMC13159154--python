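"""Assay-quality statistics and dose-response modelling.

Covers the screening-statistics layer of the pipeline: Z'-factor ranking of
imaging metrics against positive/negative control chips, normalization to
vehicle control, four-parameter-logistic (4PL) dose-response fitting with an
IC50 and normalized AUC, and readout cross-correlation.

The dose-response component follows the statsmodels idiom: build a
:class:`DoseResponseModel` from data, call :meth:`~DoseResponseModel.fit`,
and read estimates, standard errors and a ``summary()`` table off the
returned :class:`DoseResponseResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class ControlStats:
    """Means/SDs of a metric over positive- and negative-control chips."""

    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    n_pos: int = 2
    n_neg: int = 2

    def __post_init__(self) -> None:
        if self.sd_pos < 0 or self.sd_neg < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 chips per control group")

    @classmethod
    def from_values(cls, pos: np.ndarray, neg: np.ndarray) -> "ControlStats":
        pos = np.asarray(pos, dtype=np.float64)
        neg = np.asarray(neg, dtype=np.float64)
        return cls(
            mu_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)),
            mu_neg=float(neg.mean()), sd_neg=float(neg.std(ddof=1)),
            n_pos=len(pos), n_neg=len(neg),
        )


def z_prime(stats_: ControlStats) -> float:
    """Z'-factor assay-quality index.

    ``Z' = 1 − 3·(σ+ + σ−) / |μ+ − μ−|``. Values near 1 indicate an
    excellent separation between controls; Z' ≤ 0 means the control
    distributions overlap (a poor assay). Symmetric under swapping the
    control labels.
    """
    dynamic_range = abs(stats_.mu_pos - stats_.mu_neg)
    if dynamic_range == 0:
        raise ValueError("zero dynamic range: control means are equal")
    return 1.0 - 3.0 * (stats_.sd_pos + stats_.sd_neg) / dynamic_range


def rank_metrics(
    feature_table: pd.DataFrame,
    group_col: str,
    pos_label: str,
    neg_label: str,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Rank candidate imaging metrics by their Z'-factor.

    ``feature_table`` holds one row per control chip; ``group_col`` labels
    positive vs negative controls. Returns (metric, z_prime) sorted by
    descending Z', ties broken alphabetically. Metrics whose Z' is undefined
    (equal control means) get −inf.
    """
    pos = feature_table[feature_table[group_col] == pos_label]
    neg = feature_table[feature_table[group_col] == neg_label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 chips in each control group")
    if metrics is None:
        metrics = [
            c for c in feature_table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    rows = []
    for m in metrics:
        cs = ControlStats.from_values(pos[m].to_numpy(), neg[m].to_numpy())
        try:
            zp = z_prime(cs)
        except ValueError:
            zp = float("-inf")
        rows.append({"metric": m, "z_prime": zp})
    out = pd.DataFrame(rows).sort_values(
        ["z_prime", "metric"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def normalize_to_vehicle(values: np.ndarray, vehicle_values: np.ndarray) -> np.ndarray:
    """Express values as % of the vehicle-control mean (vehicle = 100%)."""
    vehicle_values = np.asarray(vehicle_values, dtype=np.float64)
    if not len(vehicle_values):
        raise ValueError("no vehicle-control values")
    mean = vehicle_values.mean()
    if mean == 0:
        raise ValueError("vehicle mean is zero; normalization undefined")
    return 100.0 * np.asarray(values, dtype=np.float64) / mean


def percent_inhibition(values: np.ndarray, vehicle_values: np.ndarray) -> np.ndarray:
    """100 − normalized response (higher = stronger drug effect)."""
    return 100.0 - normalize_to_vehicle(values, vehicle_values)


def add_vehicle_normalized(
    features: pd.DataFrame,
    feature: str = "viable_area",
    out_col: str = "normalized_viable_area",
    dose_col: str = "dose",
    vehicle_dose: float = 0.0,
) -> pd.DataFrame:
    """Fill a per-chip feature table's vehicle-normalized column (vehicle = 100%)."""
    vehicle = features.loc[features[dose_col] == vehicle_dose, feature].to_numpy()
    out = features.copy()
    out[out_col] = normalize_to_vehicle(out[feature].to_numpy(), vehicle)
    return out


# ---------------------------------------------------------------------------
# 4PL dose-response


def four_pl(logdose: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float) -> np.ndarray:
    """4PL on log10-dose; ``hill > 0`` means response falls with dose."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logdose - log_ic50)))


# minimum fitted dynamic range (response units, i.e. % of vehicle) for a fit
# to count as converged; below this the IC50 is reported "not determined"
MIN_DYNAMIC_RANGE = 5.0


class DoseResponseModel:
    """4PL dose-response model for responses expressed as % of vehicle.

    Parameters
    ----------
    doses
        Drug concentrations (µM); must be positive (the vehicle anchors the
        normalization to 100% but is excluded from the log-dose fit).
    responses
        Matched responses, typically normalized viability (% of vehicle).
    """

    def __init__(self, doses, responses):
        self.doses = np.asarray(doses, dtype=np.float64)
        self.responses = np.asarray(responses, dtype=np.float64)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be matched 1D arrays")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive (handle vehicle separately)")
        if len(np.unique(self.doses)) < 4:
            raise ValueError("need at least 4 distinct positive doses")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str = "dose",
                       response_col: str = "response") -> "DoseResponseModel":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy())

    def fit(self) -> "DoseResponseResults":
        """Multi-start least-squares 4PL fit; never raises on poor data —

        instead the results carry ``converged=False`` and an undetermined
        IC50 when the response is flat or the optimizer fails.
        """
        x = np.log10(self.doses)
        y = self.responses
        lo, hi = x.min(), x.max()
        bounds = ([0.0, 0.0, lo - 2.0, 0.05], [120.0, 120.0, hi + 2.0, 10.0])
        y_lo = float(np.clip(y.min(), 0.0, 119.0))
        y_hi = float(np.clip(y.max(), y_lo + 1e-6, 120.0))

        best = None
        for hill0 in (0.5, 1.0, 2.0):
            for lic0 in np.linspace(lo, hi, 4):
                p0 = [y_lo, y_hi, lic0, hill0]
                try:
                    popt, pcov = optimize.curve_fit(
                        four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000
                    )
                except (RuntimeError, ValueError):
                    continue
                sse = float(np.sum((four_pl(x, *popt) - y) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, popt, pcov)

        if best is None:
            return DoseResponseResults(self, None, None, converged=False)
        sse, popt, pcov = best
        converged = (popt[1] - popt[0]) >= MIN_DYNAMIC_RANGE
        return DoseResponseResults(self, popt, pcov, converged=converged)


class DoseResponseResults:
    """Fitted 4PL parameters, their uncertainties and derived quantities."""

    param_names = ("bottom", "top", "log_ic50", "hill")

    def __init__(self, model: DoseResponseModel, popt, pcov, converged: bool):
        self.model = model
        self.converged = bool(converged)
        if popt is None:
            self._popt = np.full(4, np.nan)
            self._bse = np.full(4, np.nan)
        else:
            self._popt = np.asarray(popt, dtype=np.float64)
            with np.errstate(invalid="ignore"):
                self._bse = (
                    np.sqrt(np.diag(pcov)) if pcov is not None and np.all(np.isfinite(pcov))
                    else np.full(4, np.nan)
                )

    @property
    def params(self) -> dict:
        return dict(zip(self.param_names, self._popt))

    @property
    def bse(self) -> dict:
        return dict(zip(self.param_names, self._bse))

    @property
    def bottom(self) -> float:
        return float(self._popt[0])

    @property
    def top(self) -> float:
        return float(self._popt[1])

    @property
    def hill(self) -> float:
        return float(self._popt[3])

    @property
    def ic50(self) -> float:
        """IC50 in µM; NaN ("n.d.") when the fit did not converge."""
        if not self.converged:
            return float("nan")
        return float(10.0 ** self._popt[2])

    @property
    def ic50_log10_se(self) -> float:
        return float(self._bse[2])

    def predict(self, doses) -> np.ndarray:
        doses = np.asarray(doses, dtype=np.float64)
        return four_pl(np.log10(doses), *self._popt)

    def residuals(self) -> np.ndarray:
        return self.model.responses - self.predict(self.model.doses)

    def auc(self, n_grid: int = 101) -> float:
        """AUC of the fitted curve over the observed log-dose span (see compute_auc)."""
        grid = np.linspace(np.log10(self.model.doses.min()),
                           np.log10(self.model.doses.max()), n_grid)
        return compute_auc(10.0**grid, four_pl(grid, *self._popt))

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "ic50_um": None if np.isnan(self.ic50) else self.ic50,
            **{k: (None if np.isnan(v) else float(v)) for k, v in self.params.items()},
            "bse": {k: (None if np.isnan(v) else float(v)) for k, v in self.bse.items()},
            "auc": None if np.any(np.isnan(self._popt)) else self.auc(),
        }

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "=" * 46,
            f"{'n observations':<22}{len(self.model.doses):>24}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'IC50 (uM)':<22}{('n.d.' if np.isnan(self.ic50) else format(self.ic50, '.4g')):>24}",
            "-" * 46,
            f"{'param':<10}{'estimate':>18}{'std err':>18}",
        ]
        for name, est, se in zip(self.param_names, self._popt, self._bse):
            est_s = "nan" if np.isnan(est) else format(est, ".4g")
            se_s = "nan" if np.isnan(se) else format(se, ".3g")
            lines.append(f"{name:<10}{est_s:>18}{se_s:>18}")
        if not np.any(np.isnan(self._popt)):
            lines += ["-" * 46, f"{'AUC (normalized)':<22}{self.auc():>24.4g}"]
        return "\n".join(lines)


def fit_dose_response(doses, responses) -> DoseResponseResults:
    """Convenience wrapper: build the 4PL model and fit it."""
    return DoseResponseModel(doses, responses).fit()


def compute_auc(doses, responses) -> float:
    """Trapezoidal AUC over log10-dose, normalized by the log-dose span.

    With responses in % of vehicle this lands in roughly [0, 100] and is
    comparable across drugs with different dose ranges: a constant 100%
    response gives 100, complete inhibition everywhere gives 0.
    """
    doses = np.asarray(doses, dtype=np.float64)
    responses = np.asarray(responses, dtype=np.float64)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive for a log-dose AUC")
    order = np.argsort(doses)
    x = np.log10(doses[order])
    y = responses[order]
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("need at least two distinct doses")
    return float(np.trapezoid(y, x) / span)


def correlate_readouts(x, y) -> tuple[float, int]:
    """Pearson correlation between two chip-level readouts; errors on zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need matched 1D readouts with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance readout")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(x)


def inhibition_heatmap(
    df: pd.DataFrame,
    value_col: str,
    drug_col: str = "drug",
    dose_col: str = "dose",
    vehicle_dose: float = 0.0,
) -> pd.DataFrame:
    """Percent-inhibition matrix (drugs × doses) normalized per drug to vehicle.

    Mirrors the dose-dependent survival heatmaps: red-end values (high
    inhibition) mean low cell survival. Export with ``.to_csv``.
    """
    rows = {}
    for drug, sub in df.groupby(drug_col):
        vehicle = sub.loc[sub[dose_col] == vehicle_dose, value_col].to_numpy()
        if not len(vehicle):
            raise ValueError(f"no vehicle rows for drug {drug!r}")
        treated = sub[sub[dose_col] != vehicle_dose]
        means = treated.groupby(dose_col)[value_col].mean()
        rows[drug] = pd.Series(
            percent_inhibition(means.to_numpy(), vehicle), index=means.index
        )
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = drug_col
    return out
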