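"""Moment estimators of TMRCA from linkage-disequilibrium decay.

The founder allele at a marker a recombination fraction ``theta`` away from
the disease locus is retained on a descendant chromosome with probability
``(1 - theta)**g`` after ``g`` meioses.  Writing ``p_d`` for the founder
allele's frequency on disease chromosomes and ``p_n`` for its frequency on
control chromosomes, the excess attributable to LD is

    delta = (p_d - p_n) / (1 - p_n)

and inverting the decay gives the per-marker moment estimators

    risch_g   = ln(delta) / ln(1 - theta)
    bergman_g = ln(p_d)   / ln(1 - theta)      (proportion-of-ancestral variant)

Both assume a star genealogy: every sampled disease chromosome descends
independently from the founder for the full ``g`` generations.  Under an
exponentially growing carrier population the genealogy is not star-shaped
— lineages coalesce some generations after the founding — so the moment
estimators date the TMRCA of the sample rather than the mutation itself.
:func:`labuda_correct` undoes that bias under an explicit growth model (see
:func:`growth_coalescent_correction`).

Per-marker estimates are averaged across markers
(:func:`average_tmrca`, mean +- 1.96 SE), and a composite-likelihood age
estimator over all markers and chromosomes is provided as a simplified,
clearly-labelled stand-in for full Bayesian intra-allelic genealogy methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .genetic_map import MarkerDef, kosambi_theta

__all__ = [
    "BergmanVariant",
    "MarkerAgeInput",
    "MarkerAgeEstimate",
    "TmrcaSummary",
    "CompositeAgeResult",
    "p_excess",
    "risch_g",
    "bergman_g",
    "expected_retention_under_growth",
    "growth_coalescent_correction",
    "labuda_correct",
    "informativeness_filter",
    "average_tmrca",
    "composite_likelihood_age",
    "round_half_up",
]

#: Default optimisation bound (generations) for likelihood maximisation.
DEFAULT_G_MAX = 500.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report layer only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def p_excess(p_d: float, p_n: float) -> float:
    """Excess founder-allele frequency delta = (p_d - p_n) / (1 - p_n)."""
    if not 0.0 <= p_n < 1.0:
        raise ValueError(f"control frequency p_n must be in [0, 1), got {p_n}")
    return (p_d - p_n) / (1.0 - p_n)


def _check_theta(theta: float) -> None:
    if not 0.0 < theta < 0.5:
        raise ValueError(f"recombination fraction must be in (0, 0.5), got {theta}")


def risch_g(delta: float, theta: float) -> float:
    """LD-decay moment estimator g = ln(delta) / ln(1 - theta).

    Returns 0 for a fully conserved allele (delta = 1) and ``nan`` when the
    founder allele is not enriched on disease chromosomes (delta <= 0), in
    which case no estimate exists.
    """
    _check_theta(theta)
    if delta <= 0.0:
        return math.nan
    if delta >= 1.0:
        return 0.0
    return math.log(delta) / math.log1p(-theta)


class BergmanVariant(str, Enum):
    """Which decaying quantity the Bergman-style estimator inverts."""

    #: Q = p_d, the observed proportion of ancestral haplotypes (default).
    PROPORTION = "proportion"
    #: Q = delta, the control-corrected excess (coincides with risch_g).
    DELTA = "delta"


def bergman_g(
    p_d: float,
    p_n: float,
    theta: float,
    variant: BergmanVariant = BergmanVariant.PROPORTION,
) -> float:
    """Bergman-style moment estimator.

    Inverts ``Q = (1 - theta)**g`` with ``Q`` selected by ``variant``.
    Non-informative (``nan``) when the founder allele is not enriched on
    disease chromosomes (p_d <= p_n): without enrichment the shared allele
    carries no LD signal, whichever ``Q`` is used.
    """
    _check_theta(theta)
    if not 0.0 < p_d <= 1.0:
        raise ValueError(f"disease frequency p_d must be in (0, 1], got {p_d}")
    if p_d <= p_n:
        return math.nan
    variant = BergmanVariant(variant)
    q = p_d if variant is BergmanVariant.PROPORTION else p_excess(p_d, p_n)
    if q >= 1.0:
        return 0.0
    return math.log(q) / math.log1p(-theta)


# ---------------------------------------------------------------------------
# growth correction


def expected_retention_under_growth(g: float, theta: float, p: float) -> float:
    """Expected founder-allele retention E[(1-theta)**L] at mutation age ``g``.

    Under an exponentially growing intra-allelic population (rate ``p`` per
    generation) a sampled lineage joins the founder's lineage at a time
    ``T`` after the founding with density proportional to the pairwise
    coalescent intensity 1/N(t) ~ exp(-p t), truncated to (0, g); its
    genealogical length is ``L = g - T < g``.  ``p = 0`` is taken as the
    uniform-branching limit.  The star genealogy is recovered as
    ``p -> inf`` (L -> g).
    """
    _check_theta(theta)
    if g < 0:
        raise ValueError("age must be >= 0")
    if g == 0:
        return 1.0
    a = -math.log1p(-theta)
    if p == 0.0:
        # T uniform on (0, g): (1 - exp(-a g)) / (a g)
        return -math.expm1(-a * g) / (a * g)
    den = -math.expm1(-p * g)
    if abs((a - p) * g) < 1e-8:
        # a -> p limit: p g exp(-a g) / (1 - exp(-p g))
        return p * g * math.exp(-a * g) / den
    num = p * (math.exp(-p * g) - math.exp(-a * g))
    return num / ((a - p) * den)


def growth_coalescent_correction(g_uncorrected: float, p: float, theta: float) -> float:
    """Correct a star-genealogy age estimate for exponential carrier growth.

    Solves ``E[(1-theta)**L] = (1-theta)**g_uncorrected`` for the true age
    under the growth genealogy of :func:`expected_retention_under_growth`.
    The corrected age always exceeds the star estimate for finite ``p > 0``
    (lineages are shorter than the mutation age, so the observed decay
    understates it) and approaches it as ``p -> inf``.  With ``p = 0`` no
    growth model is available and the estimate is returned unchanged.
    """
    if math.isnan(g_uncorrected):
        return math.nan
    if p < 0:
        raise ValueError("growth rate must be >= 0")
    if p == 0.0 or g_uncorrected == 0.0:
        return g_uncorrected
    _check_theta(theta)
    delta = math.exp(g_uncorrected * math.log1p(-theta))

    def f(g: float) -> float:
        return expected_retention_under_growth(g, theta, p) - delta

    lo = g_uncorrected
    if f(lo) <= 0.0:  # already at (or numerically below) the fixed point
        return g_uncorrected
    hi = max(2.0 * g_uncorrected, g_uncorrected + 4.0 / p)
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - defensive
            raise RuntimeError("growth correction failed to bracket a root")
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))


def labuda_correct(
    g_uncorrected: float,
    growth_rate: float,
    theta: float,
    correction: Callable[[float, float, float], float] | None = None,
) -> float:
    """Growth-rate correction of a per-marker moment estimate.

    ``correction`` is a pluggable callable ``(g, p, theta) -> g_corrected``;
    the default is :func:`growth_coalescent_correction`.  Non-informative
    inputs (``nan``) propagate.
    """
    if correction is None:
        correction = growth_coalescent_correction
    return correction(g_uncorrected, growth_rate, theta)


# ---------------------------------------------------------------------------
# per-marker bookkeeping


@dataclass(frozen=True)
class MarkerAgeInput:
    """Per-marker inputs to the estimators."""

    marker: MarkerDef
    p_d: float
    p_n: float
    theta: float | None = None
    founder_allele: Hashable | None = None

    def resolved_theta(self, map_function: Callable[[float], float] = kosambi_theta) -> float:
        if self.theta is not None:
            return self.theta
        return self.marker.theta(map_function)

    @property
    def delta(self) -> float:
        return p_excess(self.p_d, self.p_n)


@dataclass
class MarkerAgeEstimate:
    """Per-marker generation estimates with non-informativeness reasons."""

    marker: str
    delta: float
    bergman: float = math.nan
    risch: float = math.nan
    labuda: float = math.nan
    reasons: dict[str, str] = field(default_factory=dict)


#: Machine-readable exclusion reason codes.
REASON_NOT_ENRICHED = "allele_not_enriched"
REASON_REDUNDANT = "redundant_frequency"
REASON_NO_RECOMBINATION = "zero_recombination"
REASON_MANUAL = "manual_override"

_ESTIMATORS = ("bergman", "risch", "labuda")


def informativeness_filter(
    inputs: Sequence[MarkerAgeInput],
    estimator: str,
    overrides: Iterable[tuple[str, str, str]] = (),
) -> tuple[list[MarkerAgeInput], list[tuple[MarkerAgeInput, str]]]:
    """Split markers into informative and excluded for one estimator.

    Exclusion rules:

    * ``theta == 0`` (markers at the locus carry no recombination clock);
    * founder allele not enriched on disease chromosomes (``p_d <= p_n``,
      equivalently ``delta <= 0``);
    * for the Risch estimator (and its growth-corrected form): a marker whose
      founder-allele disease frequency equals that of its neighbour nearer
      the locus on the same side adds no recombination information and is
      dropped;
    * explicit per-marker overrides ``(marker, estimator-or-'all', reason)``,
      the mechanism for study-specific exclusions that the numeric rules do
      not capture.

    Returns ``(included, excluded)`` with a machine-readable reason per
    exclusion.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    manual = {
        name: reason
        for name, est, reason in overrides
        if est in (estimator, "all")
    }
    included: list[MarkerAgeInput] = []
    excluded: list[tuple[MarkerAgeInput, str]] = []

    # Neighbour rule needs per-side ordering by distance from the locus.
    nearer: dict[str, MarkerAgeInput] = {}
    by_side: dict[object, list[MarkerAgeInput]] = {}
    for inp in inputs:
        by_side.setdefault(inp.marker.side, []).append(inp)
    for side_inputs in by_side.values():
        side_inputs = sorted(side_inputs, key=lambda x: x.marker.genetic_distance)
        for prev, cur in zip(side_inputs, side_inputs[1:]):
            nearer[cur.marker.name] = prev

    for inp in inputs:
        name = inp.marker.name
        if name in manual:
            excluded.append((inp, f"{REASON_MANUAL}:{manual[name]}"))
            continue
        theta = inp.resolved_theta()
        if theta <= 0.0:
            excluded.append((inp, REASON_NO_RECOMBINATION))
            continue
        if inp.p_d <= inp.p_n:
            excluded.append((inp, REASON_NOT_ENRICHED))
            continue
        if estimator in ("risch", "labuda"):
            neighbour = nearer.get(name)
            if neighbour is not None and abs(inp.p_d - neighbour.p_d) < 1e-12:
                excluded.append((inp, REASON_REDUNDANT))
                continue
        included.append(inp)
    return included, excluded


# ---------------------------------------------------------------------------
# across-marker averaging


@dataclass
class TmrcaSummary:
    """Across-marker summary of per-marker generation estimates.

    ``ci95`` is mean +- 1.96 * SE with the sample (n-1) standard deviation;
    it is undefined (``None``) for a single marker.  Rounding to integers
    happens only in the report strings.
    """

    estimator: str
    markers: tuple[str, ...]
    mean: float
    se: float | None
    ci95: tuple[float, float] | None
    generation_time: float = 30.0

    @property
    def n(self) -> int:
        return len(self.markers)

    @property
    def years(self) -> float:
        return self.mean * self.generation_time

    def report(self) -> str:
        """Display string, integer-rounded, e.g. ``"35 (18-51)"``."""
        mean = round_half_up(self.mean)
        if self.ci95 is None:
            return f"{mean} (n={self.n}, CI undefined)"
        lo, hi = (round_half_up(b) for b in self.ci95)
        return f"{mean} ({lo}–{hi})"


def average_tmrca(
    per_marker: Mapping[str, float] | Sequence[float],
    generation_time: float = 30.0,
    estimator: str = "",
) -> TmrcaSummary:
    """Average per-marker generation estimates into a TMRCA summary.

    ``per_marker`` maps marker names to estimates (or is a plain sequence).
    ``nan`` entries (non-informative markers) are dropped; an empty input is
    an error.  SE uses the sample standard deviation (n-1 denominator).
    """
    if isinstance(per_marker, Mapping):
        items = [(k, v) for k, v in per_marker.items() if not math.isnan(v)]
    else:
        items = [(f"m{i + 1}", v) for i, v in enumerate(per_marker) if not math.isnan(v)]
    if not items:
        raise ValueError("no informative per-marker estimates to average")
    values = np.array([v for _, v in items], dtype=float)
    mean = float(values.mean())
    if len(values) >= 2:
        se = float(values.std(ddof=1) / math.sqrt(len(values)))
        ci = (mean - 1.96 * se, mean + 1.96 * se)
    else:
        se, ci = None, None
    return TmrcaSummary(
        estimator=estimator,
        markers=tuple(k for k, _ in items),
        mean=mean,
        se=se,
        ci95=ci,
        generation_time=generation_time,
    )


# ---------------------------------------------------------------------------
# composite-likelihood age (simplified stand-in for Bayesian LD dating)


@dataclass
class CompositeAgeResult:
    """Composite-likelihood age estimate.

    NOT a full Bayesian intra-allelic genealogy model: markers and
    chromosomes are treated as independent given the age, so the interval is
    a profile-likelihood interval of a composite likelihood and will be
    anti-conservative when the genealogy is far from star-shaped.
    """

    mle: float
    ci95: tuple[float, float]
    loglik_max: float
    at_boundary: bool = False
    grid: np.ndarray | None = None
    posterior: np.ndarray | None = None


def composite_likelihood_age(
    disease: "object",
    ancestral_alleles: Mapping[str, Hashable],
    control_freqs: Mapping[str, Mapping[Hashable, float]],
    thetas: Mapping[str, float] | None = None,
    g_max: float = DEFAULT_G_MAX,
    tol: float = 1e-6,
    prior: Callable[[np.ndarray], np.ndarray] | None = None,
    grid_size: int = 512,
) -> CompositeAgeResult:
    """Maximum composite-likelihood estimate of the mutation age.

    For each disease chromosome and marker, the observed allele is ancestral
    with probability ``(1-theta)**g + (1 - (1-theta)**g) * q(ancestral)`` and
    equals another allele ``a`` with probability ``(1 - (1-theta)**g) * q(a)``,
    where ``q`` is the control allele spectrum.  The log-likelihood is summed
    over chromosomes and markers and maximised over ``g`` in ``(0, g_max]``.

    In the single-marker case with the ancestral allele absent from controls
    this reduces analytically to :func:`risch_g` with ``delta = k/n``.

    Parameters
    ----------
    disease
        A :class:`~founderage.haplotypes.ChromosomePanel` of disease
        chromosomes.
    ancestral_alleles
        Marker name -> founder allele.
    control_freqs
        Marker name -> control allele spectrum (frequencies over alleles).
    thetas
        Marker name -> recombination fraction; defaults to each marker's
        Kosambi value.  Markers with ``theta <= 0`` are skipped.
    prior
        Optional prior density over age; when given, a normalised grid
        posterior over ``grid_size`` points is attached to the result.
    """
    markers = [m for m in disease.markers if m.name in ancestral_alleles]
    per_marker: list[tuple[float, int, list[float]]] = []  # (theta, k_anc, q_obs list)
    n_obs = 0
    all_ancestral = True
    for m in markers:
        theta = thetas[m.name] if thetas is not None else m.theta()
        if theta <= 0.0:
            continue
        anc = ancestral_alleles[m.name]
        q = control_freqs.get(m.name, {})
        q_anc = float(q.get(anc, 0.0))
        k = 0
        q_others: list[float] = []
        for allele in disease.alleles(m.name):
            n_obs += 1
            if allele == anc:
                k += 1
            else:
                all_ancestral = False
                q_others.append(max(float(q.get(allele, 0.0)), 1e-12))
        per_marker.append((theta, k, q_others, q_anc))  # type: ignore[arg-type]
    if n_obs == 0:
        raise ValueError("no usable disease calls for the composite likelihood")

    log1mt = np.array([math.log1p(-t) for t, *_ in per_marker])
    ks = np.array([k for _, k, *_ in per_marker], dtype=float)
    q_anc = np.array([qa for *_, qa in per_marker])
    sum_log_q_others = np.array(
        [sum(math.log(q) for q in q_others) for _, _, q_others, _ in per_marker]
    )
    n_others = np.array([len(q_others) for _, _, q_others, _ in per_marker], dtype=float)

    def loglik(g: float | np.ndarray) -> float | np.ndarray:
        g = np.asarray(g, dtype=float)
        r = np.exp(np.multiply.outer(g, log1mt))  # retention (1-theta)^g
        p_anc = np.clip(r + (1.0 - r) * q_anc, 1e-300, 1.0)
        p_rec = np.clip(1.0 - r, 1e-300, 1.0)
        ll = ks * np.log(p_anc) + n_others * np.log(p_rec) + sum_log_q_others
        return ll.sum(axis=-1)

    if all_ancestral:
        mle = 0.0
        at_boundary = True
        warnings.warn(
            "all disease chromosomes are fully ancestral: age estimate at the 0 boundary",
            stacklevel=2,
        )
        ll_max = float(loglik(0.0))
    else:
        res = minimize_scalar(
            lambda g: -float(loglik(g)),
            bounds=(1e-9, g_max),
            method="bounded",
            options={"xatol": tol},
        )
        mle = float(res.x)
        ll_max = -float(res.fun)
        at_boundary = mle >= g_max - 10 * tol

    # Profile-likelihood 95% interval: loglik drop of 1.92 (chi2_1 / 2).
    drop = 1.92

    def deficit(g: float) -> float:
        return float(loglik(g)) - (ll_max - drop)

    lo = 0.0 if all_ancestral else mle
    if not all_ancestral:
        lo_bound = 1e-9
        lo = lo_bound if deficit(lo_bound) > 0 else float(brentq(deficit, lo_bound, mle))
    hi = g_max if deficit(g_max) > 0 else float(brentq(deficit, max(mle, 1e-9), g_max))

    grid = posterior = None
    if prior is not None:
        grid = np.linspace(1e-6, g_max, grid_size)
        logpost = np.asarray(loglik(grid)) + np.log(np.clip(prior(grid), 1e-300, None))
        logpost -= logpost.max()
        w = np.exp(logpost)
        posterior = w / np.trapezoid(w, grid)
    return CompositeAgeResult(
        mle=mle,
        ci95=(lo, hi),
        loglik_max=ll_max,
        at_boundary=at_boundary,
        grid=grid,
        posterior=posterior,
    )
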