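"""Precision-weighted Gaussian self-appraisal.

A one-step conjugate model of conscious self-appraisal: a Gaussian prior
(top-down self-beliefs) is fused with a Gaussian likelihood (bottom-up
affective evidence from the internal working model of the self) on a signed
valence axis — negative means shame/worthlessness, positive means positive
self-regard.  The posterior mean is the precision-weighted average of the
two means, so shifting precision between prior and evidence moves the
posterior without changing either message's content.

Three named scenarios capture trait patterns:

``undefended``
    modest positive prior, strong negative evidence -> negative posterior;
``self_aggrandizing``
    elevated and over-precise prior -> positive posterior despite the same
    negative evidence;
``lacks_remorse``
    neutral prior, evidence precision attenuated -> near-zero posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ParameterError

#: Default half-width of the neutral valence band (boundary inclusive).
NEUTRAL_THRESHOLD = 0.25


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian belief over valence, parameterized as (mean, precision)."""

    mean: float
    precision: float

    def __post_init__(self) -> None:
        if not (self.precision > 0):
            raise ParameterError("precision: must be > 0")
        if not abs(self.mean) < float("inf"):
            raise ParameterError("mean: must be finite")

    @property
    def variance(self) -> float:
        return 1.0 / self.precision


@dataclass(frozen=True)
class AppraisalScenario:
    name: str
    prior: GaussianBelief
    likelihood: GaussianBelief
    posterior: GaussianBelief
    valence: str  # classify_valence(posterior)


def fuse(prior: GaussianBelief, likelihood: GaussianBelief) -> GaussianBelief:
    """Exact conjugate Gaussian fusion: precisions add, the posterior mean
    is the precision-weighted average of the input means."""
    precision = prior.precision + likelihood.precision
    mean = (prior.precision * prior.mean
            + likelihood.precision * likelihood.mean) / precision
    return GaussianBelief(mean=mean, precision=precision)


def classify_valence(belief: GaussianBelief,
                     threshold: float = NEUTRAL_THRESHOLD) -> str:
    """Label the belief's mean as negative / neutral / positive with a
    closed neutral band ``[-threshold, +threshold]``."""
    if not (threshold > 0):
        raise ParameterError("threshold: must be > 0")
    if belief.mean < -threshold:
        return "negative"
    if belief.mean > threshold:
        return "positive"
    return "neutral"


#: Scenario presets on a [-2, +2] valence scale.  The evidence from the
#: self-schema is negative (shame/worthlessness) throughout; only means and
#: precisions of the messages differ between scenarios.
SCENARIO_PRESETS: dict[str, tuple[GaussianBelief, GaussianBelief]] = {
    "undefended": (GaussianBelief(mean=0.5, precision=1.0),
                   GaussianBelief(mean=-1.5, precision=4.0)),
    "self_aggrandizing": (GaussianBelief(mean=1.5, precision=16.0),
                          GaussianBelief(mean=-1.5, precision=4.0)),
    "lacks_remorse": (GaussianBelief(mean=0.0, precision=1.0),
                      GaussianBelief(mean=-1.5, precision=0.05)),
}


def scenario(name: str,
             prior: GaussianBelief | None = None,
             likelihood: GaussianBelief | None = None) -> AppraisalScenario:
    """Build a named scenario from its preset (or overridden) prior and
    likelihood; the posterior is always computed by :func:`fuse`."""
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown scenario {name!r}; choose from "
                       f"{sorted(SCENARIO_PRESETS)}")
    preset_prior, preset_likelihood = SCENARIO_PRESETS[name]
    prior = preset_prior if prior is None else prior
    likelihood = preset_likelihood if likelihood is None else likelihood
    posterior = fuse(prior, likelihood)
    return AppraisalScenario(name=name, prior=prior, likelihood=likelihood,
                             posterior=posterior,
                             valence=classify_valence(posterior))
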