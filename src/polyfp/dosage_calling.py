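"""Allele-dosage calling from two-channel endpoint fluorescence.

A tetraploid carries 0-4 copies of the B allele of a biallelic SNP, so the
transformed signal ratio b/(a+b) of an allele-specific PCR falls into one of
five clusters along [0, 1]. Calling fits a 5-component Gaussian mixture with
strictly ordered component locations to the ratios of all samples in one
*analysis unit* (the group of samples modelled together — a pooled 384-well
plate or one 95-sample source plate), then assigns each sample the posterior
argmax class when its posterior clears a confidence threshold (default 0.95)
and leaves it missing otherwise.

The EM here is deliberately deterministic: component locations initialise at
evenly spaced quantiles of the empirical ratios, weights start uniform and
scales at the pooled MAD, so identical inputs always give identical calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, UsageError, ValidationError
from .io_formats import ScoreMatrix, SignalRecord

__all__ = [
    "CallerConfig",
    "DosageMixtureFit",
    "DosageCall",
    "transform_signal",
    "fit_dosage_mixture",
    "call_dosages",
    "call_rate",
    "flag_plates_for_repeat",
    "posterior_matrix",
    "call_layout",
]

_SCALE_FLOOR = 1e-4
_WEIGHT_FLOOR = 1e-6
_MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class CallerConfig:
    """Settings for the dosage caller.

    ``posterior_threshold`` mirrors the calling package's p.threshold: a
    sample is scored only when its best class posterior reaches the
    threshold. ``dip_filter`` is accepted for interface parity but is a
    no-op (the pipeline runs with it off).
    """

    ploidy: int = 4
    posterior_threshold: float = 0.95
    dip_filter: bool = False
    max_iterations: int = 500
    convergence_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.posterior_threshold < 1:
            raise ValidationError(
                "posterior_threshold must lie in (0.5, 1), got "
                f"{self.posterior_threshold}"
            )
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")

    @property
    def n_classes(self) -> int:
        return self.ploidy + 1


@dataclass
class DosageMixtureFit:
    """A fitted ordered-location mixture for one marker x analysis unit."""

    marker_id: str
    unit_id: str
    locations: np.ndarray
    scales: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    n_samples: int

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.diff(self.locations) > 0):
            raise ValidationError("mixture locations must be strictly increasing")
        if not np.all(self.scales > 0):
            raise ValidationError("mixture scales must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class DosageCall:
    """One sample's dosage assignment for one marker in one analysis unit.

    ``dosage`` is None when the best posterior misses the threshold or the
    sample was unprocessable; ``posterior`` then still records the best
    class posterior (0.0 for unprocessable samples).
    """

    sample_id: str
    marker_id: str
    unit_id: str
    dosage: int | None
    posterior: float
    source_plate_id: str = ""
    is_negative_control: bool = False


def transform_signal(signal_a: float, signal_b: float) -> float:
    """Map two-channel fluorescence to the B-allele ratio b/(a+b).

    Both channels zero means the reaction produced no signal; the sample is
    unprocessable and NaN is returned (callers translate it into a missing
    call rather than an exception).
    """
    if signal_a < 0 or signal_b < 0:
        raise ValidationError("signals must be non-negative")
    total = signal_a + signal_b
    if total == 0:
        return float("nan")
    return float(signal_b / total)


def _usable_ratios(
    records: Sequence[SignalRecord],
) -> tuple[np.ndarray, list[SignalRecord]]:
    usable = []
    ratios = []
    for rec in records:
        if rec.is_negative_control:
            continue
        r = transform_signal(rec.signal_a, rec.signal_b)
        if np.isnan(r):
            continue
        usable.append(rec)
        ratios.append(r)
    return np.asarray(ratios, dtype=float), usable


def _check_single_unit(records: Sequence[SignalRecord]) -> tuple[str, str]:
    markers = {r.marker_id for r in records}
    units = {r.analysis_plate_id for r in records}
    if len(markers) != 1 or len(units) != 1:
        raise UsageError(
            f"records span markers {sorted(markers)} and units "
            f"{sorted(units)}; fit one marker x one analysis unit at a time"
        )
    return markers.pop(), units.pop()


def fit_dosage_mixture(
    records: Sequence[SignalRecord],
    config: CallerConfig | None = None,
    unit_id: str | None = None,
) -> DosageMixtureFit:
    """Fit the ordered 5-component Gaussian mixture to one marker x unit.

    Negative controls and zero-signal wells are excluded; at least
    ``n_classes`` usable records are required. EM runs with the component
    order constraint enforced by construction (quantile initialisation plus
    per-iteration sorting) and per-class scales floored at 1e-4 and weights
    floored at 1e-6 to keep sparse classes alive.
    """
    if config is None:
        config = CallerConfig()
    marker_id, rec_unit = _check_single_unit(records)
    if unit_id is None:
        unit_id = rec_unit
    x, usable = _usable_ratios(records)
    k = config.n_classes
    if len(x) < k:
        raise FitError(
            f"marker {marker_id!r}, unit {unit_id!r}: only {len(x)} usable "
            f"records; need at least {k}"
        )

    # Stage 1: EM with locations constrained affine in dosage
    # (mu_d = alpha + beta*d, beta > 0). The constraint keeps class labels
    # identified even when a dosage class is absent from the unit — the
    # occupied clusters pin down alpha and beta and the empty class's
    # location follows, instead of the components sliding onto the wrong
    # clusters. Stage 2: free-location refinement from the constrained
    # solution, accepted only when it improves the likelihood without
    # moving any location by more than half the class spacing (which would
    # re-label classes and defeat the point of the constraint).
    ll_c, mu_c, sigma_c, w_c, conv_c = _run_em_affine(x, config)
    spacing = float(np.min(np.diff(mu_c)))
    if spacing <= max(2 * _MIN_SPACING, 2 * float(np.median(sigma_c))):
        # effectively monomorphic: class spacing below the component
        # scales, so the clusters are unresolvable. Anchor the single
        # cluster to the dosage whose canonical ratio d/ploidy is nearest
        # and give that class the weight.
        prev_ll, mu, sigma, w = _monomorphic_solution(x, config)
        converged = True
    else:
        prev_ll, mu, sigma, w, converged = ll_c, mu_c, sigma_c, w_c, conv_c
        ll_f, mu_f, sigma_f, w_f, conv_f = _run_em(x, mu_c, config)
        if ll_f > ll_c and np.all(np.abs(mu_f - mu_c) < spacing / 2):
            prev_ll, mu, sigma, w, converged = ll_f, mu_f, sigma_f, w_f, conv_f

    return DosageMixtureFit(
        marker_id=marker_id,
        unit_id=unit_id,
        locations=mu,
        scales=sigma,
        weights=w,
        log_likelihood=prev_ll,
        converged=converged,
        n_samples=len(x),
    )


_MIN_SPACING = 1e-3  # smallest per-dosage spacing on the ratio axis


def _log_resp(x, mu, sigma, w):
    log_dens = (
        -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        - np.log(sigma[None, :])
        - 0.5 * np.log(2 * np.pi)
        + np.log(w[None, :])
    )
    m = log_dens.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
    return float(lse.sum()), np.exp(log_dens - lse[:, None])


def _monomorphic_solution(
    x: np.ndarray, config: CallerConfig
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Degenerate fit for a single tight cluster.

    The cluster takes (nearly) all the weight in the dosage class whose
    canonical ratio d/ploidy lies nearest its centre; the remaining
    components sit on the canonical spacing with floored weights.
    """
    k = config.n_classes
    centre = float(np.mean(x))
    sd = max(float(np.std(x)), _SCALE_FLOOR)
    d_star = int(np.argmin(np.abs(centre - np.arange(k) / config.ploidy)))
    beta = 1.0 / config.ploidy
    mu = centre + (np.arange(k) - d_star) * beta
    sigma = np.full(k, sd)
    w = np.full(k, _WEIGHT_FLOOR)
    w[d_star] = 1.0 - (k - 1) * _WEIGHT_FLOOR
    ll, _ = _log_resp(x, mu, sigma, w)
    return ll, mu, sigma, w


def _run_em_affine(
    x: np.ndarray, config: CallerConfig
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM with component locations constrained to mu_d = alpha + beta*d.

    Initialisation uses the canonical cluster geometry of the transformed
    ratio axis — dosage-d clusters near 0.1 + 0.8*(d/ploidy), pulled
    slightly inward from the axis ends as allele-specific PCR chemistry
    produces — which anchors the dosage labelling when only a subset of
    classes is present in the unit. The M-step's weighted least squares
    then adapts alpha and beta to the data.
    """
    k = config.n_classes
    t = np.arange(k, dtype=float)
    beta = 0.8 / (k - 1)
    alpha = 0.1
    mu = alpha + beta * t
    mad = np.median(np.abs(x - np.median(x)))
    sigma = np.full(k, max(_MAD_TO_SIGMA * mad / k, _SCALE_FLOOR))
    w = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    converged = False
    for _ in range(config.max_iterations):
        ll, resp = _log_resp(x, mu, sigma, w)
        nk = resp.sum(axis=0)
        w = np.maximum(nk / len(x), _WEIGHT_FLOOR)
        w = w / w.sum()
        # weighted least squares for (alpha, beta), weights r_id / sigma_d^2
        wls = resp / sigma[None, :] ** 2
        s_w = wls.sum()
        s_t = (wls * t[None, :]).sum()
        s_tt = (wls * t[None, :] ** 2).sum()
        s_x = (wls * x[:, None]).sum()
        s_xt = (wls * (x[:, None] * t[None, :])).sum()
        denom = s_w * s_tt - s_t**2
        if denom > 1e-12:
            beta = (s_w * s_xt - s_t * s_x) / denom
            beta = max(beta, _MIN_SPACING)
            alpha = (s_x - beta * s_t) / s_w
        mu = alpha + beta * t
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0)
        sigma = np.sqrt(
            np.maximum(var / np.maximum(nk, 1e-12), _SCALE_FLOOR**2)
        )
        if abs(ll - prev_ll) < config.convergence_tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, mu, sigma, w, converged


def _run_em(
    x: np.ndarray, mu0: np.ndarray, config: CallerConfig
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Free-location EM for the ordered mixture from one initialisation."""
    k = config.n_classes
    mu = np.array(mu0, dtype=float)
    # enforce strict ordering when initial locations tie on granular data
    for i in range(1, k):
        if mu[i] <= mu[i - 1]:
            mu[i] = mu[i - 1] + 1e-6
    mad = np.median(np.abs(x - np.median(x)))
    sigma = np.full(k, max(_MAD_TO_SIGMA * mad / k, _SCALE_FLOOR))
    w = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    converged = False
    for _ in range(config.max_iterations):
        log_dens = (
            -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_dens - lse[:, None])

        nk = resp.sum(axis=0)
        w = np.maximum(nk / len(x), _WEIGHT_FLOOR)
        w = w / w.sum()
        mu_new = np.where(nk > 0, resp.T @ x / np.maximum(nk, 1e-12), mu)
        var = (resp * (x[:, None] - mu_new[None, :]) ** 2).sum(axis=0)
        sigma = np.sqrt(np.maximum(var / np.maximum(nk, 1e-12), _SCALE_FLOOR**2))
        mu = mu_new
        order = np.argsort(mu)
        mu, sigma, w = mu[order], sigma[order], w[order]
        for i in range(1, k):
            if mu[i] <= mu[i - 1]:
                mu[i] = mu[i - 1] + 1e-9
        if abs(ll - prev_ll) < config.convergence_tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    return prev_ll, mu, sigma, w, converged


def posterior_matrix(fit: DosageMixtureFit, ratios: np.ndarray) -> np.ndarray:
    """Class posteriors (Bayes rule on the fitted mixture) for given ratios.

    Rows sum to 1; NaN ratios yield NaN rows.
    """
    ratios = np.asarray(ratios, dtype=float)
    mu, sigma, w = fit.locations, fit.scales, fit.weights
    ok = ~np.isnan(ratios)
    p = np.full((len(ratios), len(mu)), np.nan)
    if ok.any():
        log_dens = (
            -0.5 * ((ratios[ok, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            + np.log(w[None, :])
        )
        m = log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens - m)
        p[ok] = dens / dens.sum(axis=1, keepdims=True)
    return p


def call_dosages(
    fit: DosageMixtureFit,
    records: Sequence[SignalRecord],
    config: CallerConfig | None = None,
) -> list[DosageCall]:
    """Assign dosages from a fitted mixture.

    Each non-control record gets the posterior-argmax class when the best
    posterior reaches ``posterior_threshold``; otherwise the call is
    missing. Negative controls and zero-signal wells are reported as missing
    with posterior 0.
    """
    if config is None:
        config = CallerConfig()
    for rec in records:
        if rec.marker_id != fit.marker_id:
            raise UsageError(
                f"record marker {rec.marker_id!r} does not match fit marker "
                f"{fit.marker_id!r}"
            )
    calls: list[DosageCall] = []
    ratios = np.array(
        [transform_signal(r.signal_a, r.signal_b) for r in records]
    )
    post = posterior_matrix(fit, ratios)
    for rec, row in zip(records, post):
        if rec.is_negative_control or np.any(np.isnan(row)):
            calls.append(
                DosageCall(
                    sample_id=rec.sample_id,
                    marker_id=rec.marker_id,
                    unit_id=fit.unit_id,
                    dosage=None,
                    posterior=0.0,
                    source_plate_id=rec.source_plate_id,
                    is_negative_control=rec.is_negative_control,
                )
            )
            continue
        best = int(np.argmax(row))
        p_best = float(row[best])
        dosage = best if p_best >= config.posterior_threshold else None
        calls.append(
            DosageCall(
                sample_id=rec.sample_id,
                marker_id=rec.marker_id,
                unit_id=fit.unit_id,
                dosage=dosage,
                posterior=p_best,
                source_plate_id=rec.source_plate_id,
                is_negative_control=rec.is_negative_control,
            )
        )
    return calls


def call_rate(calls: Iterable[DosageCall]) -> float:
    """Fraction of non-control samples with an assigned dosage."""
    non_control = [c for c in calls if not c.is_negative_control]
    if not non_control:
        raise ValidationError("call rate undefined for an empty collection")
    called = sum(1 for c in non_control if c.dosage is not None)
    return called / len(non_control)


def flag_plates_for_repeat(
    calls: Iterable[DosageCall], threshold: float = 0.20
) -> list[str]:
    """Source plates whose missing fraction strictly exceeds the threshold.

    Mirrors the lab rule of repeating the assay for DNA plates where more
    than 20% of the genotypes could not be scored.
    """
    by_plate: dict[str, list[DosageCall]] = {}
    for c in calls:
        if c.is_negative_control:
            continue
        by_plate.setdefault(c.source_plate_id, []).append(c)
    flagged = []
    for plate, plate_calls in sorted(by_plate.items()):
        missing = sum(1 for c in plate_calls if c.dosage is None)
        if missing / len(plate_calls) > threshold:
            flagged.append(plate)
    return flagged


def call_layout(
    records: Sequence[SignalRecord],
    layout: str = "original",
    config: CallerConfig | None = None,
) -> tuple[ScoreMatrix, dict[tuple[str, str], DosageMixtureFit]]:
    """Call every marker under one analysis-unit scheme.

    ``layout="original"`` models each (marker, analysis plate) group jointly;
    ``layout="single"`` splits each analysis plate back into its 95-sample
    source plates and fits each separately. Returns the resulting
    :class:`ScoreMatrix` (with per-cell posteriors attached) and the fits
    keyed by (marker, unit). Units that cannot be fitted leave their cells
    missing.
    """
    if config is None:
        config = CallerConfig()
    if layout not in ("original", "single"):
        raise UsageError(f"unknown layout {layout!r}")

    def unit_of(rec: SignalRecord) -> str:
        if layout == "original":
            return rec.analysis_plate_id
        return f"{rec.analysis_plate_id}:{rec.source_plate_id}"

    groups: dict[tuple[str, str], list[SignalRecord]] = {}
    for rec in records:
        groups.setdefault((rec.marker_id, unit_of(rec)), []).append(rec)

    samples = sorted({r.sample_id for r in records if not r.is_negative_control})
    markers = sorted({r.marker_id for r in records})
    scores = pd.DataFrame(np.nan, index=samples, columns=markers)
    posts = pd.DataFrame(np.nan, index=samples, columns=markers)
    fits: dict[tuple[str, str], DosageMixtureFit] = {}
    for (marker, unit), recs in sorted(groups.items()):
        # for the single layout, fit on the source-plate subgroup but keep
        # the analysis-plate tag so provenance stays recoverable
        recs_unit = [r for r in recs]
        try:
            fit = fit_dosage_mixture(recs_unit, config, unit_id=unit)
        except FitError:
            continue
        fits[(marker, unit)] = fit
        for call in call_dosages(fit, recs_unit, config):
            if call.is_negative_control:
                continue
            if call.dosage is not None:
                scores.loc[call.sample_id, marker] = call.dosage
            posts.loc[call.sample_id, marker] = call.posterior
    return ScoreMatrix(scores, layout=layout, posteriors=posts), fits
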