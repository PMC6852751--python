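"""Quantitative phenotype computations for transgenic-line characterization.

Covers the growth-curve machinery (four-parameter logistic fit and the
rapid-growth-stage quantities derived from it), detergent-fiber wood
composition, wood basic density, leaf-anatomy ratios, instantaneous water-use
efficiency, qPCR relative expression (2^-ddCT), and ORF finding/translation.

The logistic model is H(t) = a + (b - a) / (1 + exp(-k (t - t0))) with a the
lower and b the upper height asymptote (cm), k the rate (1/day) and t0 the
inflection day. The rapid growth stage is bounded by the zeros of the third
derivative of H, t0 +/- ln(2 + sqrt(3))/k, the standard convention; growth
inside the stage has the closed form (b - a)/sqrt(3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import curve_fit

from .io_formats import revcomp

__all__ = [
    "GrowthSeries",
    "LogisticFit",
    "RapidStage",
    "WoodAssay",
    "WoodComposition",
    "DdCtInput",
    "FitError",
    "fit_logistic4",
    "rapid_stage",
    "daily_growth",
    "wood_composition",
    "basic_density",
    "leaf_ratios",
    "wue",
    "fold_change_ddct",
    "find_orf_and_translate",
]

RAPID_STAGE_HALF_WIDTH = math.log(2 + math.sqrt(3))  # in units of 1/k


class FitError(RuntimeError):
    """Raised when the logistic fit fails; carries the best fit so far."""

    def __init__(self, message: str, best: "LogisticFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GrowthSeries:
    """Height observations (day since season start, height in cm)."""

    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.observations]
        if len(days) < 5:
            raise ValueError("need at least 5 observations to fit")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(h < 0 for _, h in self.observations):
            raise ValueError("heights must be >= 0")

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, h in self.observations], dtype=float)


@dataclass(frozen=True)
class LogisticFit:
    a: float  # height at the beginning of growth (cm), lower asymptote
    b: float  # height at the end of growth (cm), upper asymptote
    k: float  # rate (1/day)
    t0: float  # inflection day
    r2: float

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        return logistic4(t, self.a, self.b, self.k, self.t0)


@dataclass(frozen=True)
class RapidStage:
    """Rapid-growth-stage quantities, reported at two decimals."""

    t1: float  # stage start (d)
    t2: float  # stage end (d)
    rr: float  # duration t2 - t1 (d)
    t0: float  # day of maximum growth rate (d)
    vmax: float  # maximum growth rate (cm/d)
    gr: float  # growth during the stage (cm)
    gd: float  # mean daily growth gr/rr (cm/d)
    rra: float  # 100 * gr / annual growth (%)


def logistic4(t, a, b, k, t0):
    return a + (b - a) / (1.0 + np.exp(-k * (t - t0)))


def fit_logistic4(
    series: GrowthSeries,
    init: tuple[float, float, float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> LogisticFit:
    """Nonlinear least squares fit of the four-parameter logistic.

    Default initialization: a = min height, b = max height, t0 = day of the
    median height, k from the steepest finite-difference slope scaled by
    4/(b - a) (the slope at the inflection of the model).
    """
    t = series.days
    h = series.heights
    if np.ptp(h) == 0:
        raise FitError("degenerate series: all heights equal")
    if init is None:
        a0, b0 = float(h.min()), float(h.max())
        med = float(np.median(h))
        t0_0 = float(t[np.argmin(np.abs(h - med))])
        slopes = np.diff(h) / np.diff(t)
        k0 = max(1e-4, 4.0 * float(np.max(np.abs(slopes))) / (b0 - a0))
        init = (a0, b0, k0, t0_0)
    try:
        popt, _ = curve_fit(
            logistic4,
            t,
            h,
            p0=init,
            maxfev=max_iter * 10,
            ftol=tol,
            xtol=tol,
        )
    except RuntimeError as err:
        best = LogisticFit(*init, r2=_r2(h, logistic4(t, *init)))
        raise FitError(f"logistic fit did not converge: {err}", best=best) from err
    a, b, k, t0 = (float(v) for v in popt)
    if k < 0:  # mirrored parameterization; normalize
        a, b, k = b, a, -k
    fit = LogisticFit(a, b, k, t0, r2=_r2(h, logistic4(t, a, b, k, t0)))
    if fit.b <= fit.a:
        raise FitError("degenerate optimum: b <= a", best=fit)
    return fit


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else float("nan")


def daily_growth(gr: float, rr: float) -> float:
    """Mean daily growth over the rapid stage (cm/d), at two decimals."""
    if rr <= 0:
        raise ValueError("stage duration must be positive")
    return round(gr / rr, 2)


def rapid_stage(fit: LogisticFit, annual_growth: float) -> RapidStage:
    """Rapid-stage quantities from a fit.

    t1, t2 are the third-derivative zeros t0 -/+ ln(2+sqrt(3))/k; the stage
    growth has the closed form (b-a)/sqrt(3) and the peak rate k(b-a)/4.
    ``annual_growth`` (cm) is the measured season total used as the
    denominator of the stage share RRA.
    """
    if annual_growth <= 0:
        raise ValueError("annual_growth must be positive")
    half = RAPID_STAGE_HALF_WIDTH / fit.k
    t1, t2 = fit.t0 - half, fit.t0 + half
    rr = t2 - t1
    gr = float(fit.predict(t2) - fit.predict(t1))  # == (b-a)/sqrt(3)
    vmax = fit.k * (fit.b - fit.a) / 4.0
    return RapidStage(
        t1=round(t1, 2),
        t2=round(t2, 2),
        rr=round(rr, 2),
        t0=round(fit.t0, 2),
        vmax=round(vmax, 2),
        gr=round(gr, 2),
        gd=daily_growth(gr, rr),
        rra=round(100.0 * gr / annual_growth, 2),
    )


# ------------------------------------------------------------ wood


@dataclass(frozen=True)
class WoodAssay:
    """Sequential detergent-fiber residues, percent of dry mass."""

    ndf: float
    adf: float
    adl: float
    ash: float

    def __post_init__(self) -> None:
        if not 0 <= self.ash <= self.adl <= self.adf <= self.ndf <= 100:
            raise ValueError("assay must satisfy 0 <= ash <= ADL <= ADF <= NDF <= 100")


@dataclass(frozen=True)
class WoodComposition:
    hemicellulose: float
    holocellulose: float
    cellulose: float
    lignin: float


def wood_composition(assay: WoodAssay) -> WoodComposition:
    """Difference formulas: hemicellulose = NDF - ADF, holocellulose =
    NDF - ADL, cellulose = ADF - ADL, lignin = ADL - ash. The identity
    holocellulose = hemicellulose + cellulose holds algebraically."""
    return WoodComposition(
        hemicellulose=assay.ndf - assay.adf,
        holocellulose=assay.ndf - assay.adl,
        cellulose=assay.adf - assay.adl,
        lignin=assay.adl - assay.ash,
    )


def basic_density(dry_mass_g: float, saturated_volume_cm3: float) -> float:
    """Wood basic density: oven-dry mass over water-saturated volume."""
    if saturated_volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return dry_mass_g / saturated_volume_cm3


def leaf_ratios(palisade_um: float, spongy_um: float, leaf_um: float) -> dict[str, float]:
    """Palisade/spongy ratio, palisade tightness (CTR) and spongy share (SR)."""
    if min(palisade_um, spongy_um, leaf_um) <= 0:
        raise ValueError("thicknesses must be positive")
    return {
        "ratio_ps": palisade_um / spongy_um,
        "ctr": palisade_um / leaf_um,
        "sr": spongy_um / leaf_um,
    }


def wue(pn: float, tr: float) -> float:
    """Instantaneous water-use efficiency Pn/Tr."""
    if tr <= 0:
        raise ValueError("transpiration rate must be positive")
    return pn / tr


@dataclass(frozen=True)
class DdCtInput:
    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float


def fold_change_ddct(inp: DdCtInput) -> float:
    """Relative expression by the 2^-ddCT method."""
    ddct = (inp.ct_target_sample - inp.ct_ref_sample) - (
        inp.ct_target_calibrator - inp.ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


# ------------------------------------------------------------ ORF

_STOPS = {"TAA", "TAG", "TGA"}


def find_orf_and_translate(seq: str, min_len: int = 90) -> dict | None:
    """Longest ATG-initiated open reading frame ending in a stop codon,
    searched on both strands with the standard genetic code.

    Returns {orf_start, orf_len, strand, protein} with orf_start the 1-based
    position of the ATG on the reported strand and orf_len including the stop
    codon (protein length = orf_len/3 - 1); None when no ORF reaches
    ``min_len`` nucleotides.
    """
    seq = seq.upper()
    best: tuple[int, int, str] | None = None  # (length, start, strand)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start: int | None = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in _STOPS:
                    length = i + 3 - start
                    cand = (length, start, strand)
                    if best is None or length > best[0] or (
                        length == best[0]
                        and (start, strand) < (best[1], best[2])
                    ):
                        best = cand
                    start = None
    if best is None or best[0] < min_len:
        return None
    length, start, strand = best
    s = seq if strand == "+" else revcomp(seq)
    orf = s[start : start + length]
    protein = str(Seq(orf).translate())[:-1]  # drop trailing '*'
    return {
        "orf_start": start + 1,
        "orf_len": length,
        "strand": strand,
        "protein": protein,
    }
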