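"""Apical-endpoint summaries and exposure-dose confirmation.

Covers mortality / edema / hatching bookkeeping per dose group, a two-sided
exact test comparing hatching against control at 48 hpf, internal-standard
calibrated quantification of exposure medium, percent-of-nominal checks and
replicate RSDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EMBRYO_ROLES


def _round_half_away(x: float) -> int:
    """Nearest-integer rounding with ties away from zero (so 11/12 -> 92%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class EndpointSummary:
    group: str
    n_embryos: int
    n_dead: int
    n_edema: int
    n_hatched_48hpf: int

    @property
    def pct_dead(self) -> int:
        return _round_half_away(100.0 * self.n_dead / self.n_embryos)

    @property
    def pct_edema(self) -> int:
        return _round_half_away(100.0 * self.n_edema / self.n_embryos)

    @property
    def pct_hatched(self) -> int:
        return _round_half_away(100.0 * self.n_hatched_48hpf / self.n_embryos)

    def to_dict(self) -> dict:
        return dict(
            group=self.group, n_embryos=self.n_embryos, n_dead=self.n_dead,
            n_edema=self.n_edema, n_hatched_48hpf=self.n_hatched_48hpf,
            pct_dead=self.pct_dead, pct_edema=self.pct_edema, pct_hatched=self.pct_hatched,
        )


def summarize_endpoints(samples: pd.DataFrame) -> dict[str, EndpointSummary]:
    """Counts and integer percentages per exposure group.

    `samples` is the sample-metadata frame; only embryo rows (dose groups and
    controls) carry endpoints.
    """
    embryos = samples[samples["role"].isin(EMBRYO_ROLES)]
    out: dict[str, EndpointSummary] = {}
    for group, sub in embryos.groupby("group", sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group: {group}")
        out[str(group)] = EndpointSummary(
            group=str(group),
            n_embryos=len(sub),
            n_dead=int((sub["dead_120hpf"] == True).sum()),  # noqa: E712 (NA -> False)
            n_edema=int((sub["edema"] == True).sum()),  # noqa: E712
            n_hatched_48hpf=int((sub["hatched_48hpf"] == True).sum()),  # noqa: E712
        )
    if not out:
        raise ValueError("no embryo samples found")
    return out


def hatching_comparison(group: EndpointSummary, control: EndpointSummary) -> float:
    """Two-sided exact (Fisher) test on the 2x2 hatched/not-hatched table."""
    if group.n_embryos == 0 or control.n_embryos == 0:
        raise ValueError("both arms need at least one embryo")
    table = [
        [group.n_hatched_48hpf, group.n_embryos - group.n_hatched_48hpf],
        [control.n_hatched_48hpf, control.n_embryos - control.n_hatched_48hpf],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class CalibrationCurve:
    """Linear calibration of IS-normalized response versus concentration."""

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    weighting: str = "none"

    @classmethod
    def fit(cls, concentrations, responses, weighting: str = "none") -> "CalibrationCurve":
        c = np.asarray(concentrations, float)
        r = np.asarray(responses, float)
        if len(c) < 3:
            raise ValueError("calibration needs >= 3 points")
        w = np.ones_like(c) if weighting == "none" else 1.0 / c
        W = np.diag(w)
        A = np.column_stack([c, np.ones_like(c)])
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ r)
        slope, intercept = float(beta[0]), float(beta[1])
        if slope <= 0:
            raise ValueError("calibration slope must be positive")
        return cls(c, r, slope, intercept, weighting)


@dataclass
class DoseCheck:
    nominal: float
    measured: float
    replicate_rsd_pct: float
    percent_nominal: int
    extrapolated: bool = False


def quantify_dose(
    curve: CalibrationCurve, response: float, dilution_factor: float = 1.0
) -> tuple[float, bool]:
    """Back-calculate a concentration (ug/L); flags extrapolation beyond the
    calibration range."""
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    conc = dilution_factor * (response - curve.intercept) / curve.slope
    in_range = curve.responses.min() <= response <= curve.responses.max()
    return float(conc), not in_range


def percent_of_nominal(measured: float, nominal: float) -> int:
    """100 * measured / nominal, to the nearest integer."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return _round_half_away(100.0 * measured / nominal)


def replicate_rsd(values) -> float:
    """Relative standard deviation in % (sample sd / mean)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("RSD needs >= 2 replicate values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for RSD")
    return float(100.0 * v.std(ddof=1) / mean)


def check_doses(
    curve: CalibrationCurve,
    replicate_responses: dict[float, list[float]],
    dilution_factors: dict[float, float] | None = None,
) -> list[DoseCheck]:
    """Dose confirmation for each nominal level from replicate IS-normalized
    responses of the exposure medium."""
    out = []
    for nominal, responses in sorted(replicate_responses.items()):
        df = (dilution_factors or {}).get(nominal, 1.0)
        concs, flags = zip(*(quantify_dose(curve, r, df) for r in responses))
        measured = float(np.mean(concs))
        out.append(
            DoseCheck(
                nominal=nominal,
                measured=measured,
                replicate_rsd_pct=replicate_rsd(concs),
                percent_nominal=percent_of_nominal(measured, nominal),
                extrapolated=any(flags),
            )
        )
    return out
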