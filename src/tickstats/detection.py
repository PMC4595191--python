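"""Herd-level probability of detecting tick presence from a finite sample.

Freedom-from-infestation style calculation: given a design prevalence and
an inspection sensitivity per examination mode (detailed examination of
laid-down animals vs. a quicker corridor check), the probability that a
sample from an infested herd yields at least one detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HerdSample:
    """Sampling effort and detection assumptions for one herd.

    Defaults: design prevalence 20 %, sensitivity 1.0 for laid-down
    inspections and 0.6 for corridor inspections.  When ``herd_size`` is
    given the finite-population (hypergeometric) variant applies.
    """

    n_laid_down: int
    n_corridor: int = 0
    prevalence: float = 0.20
    se_laid: float = 1.0
    se_corridor: float = 0.6
    herd_size: int | None = None

    def __post_init__(self) -> None:
        for name in ("prevalence", "se_laid", "se_corridor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_laid_down < 0 or self.n_corridor < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.herd_size is not None and \
                self.n_laid_down + self.n_corridor > self.herd_size:
            raise ValueError("sample exceeds herd size")


def detect_prob(sample: HerdSample) -> float:
    """Probability of at least one tick detection in the sample.

    Binomial form:
    ``1 - (1 - prevalence * se_laid)^n_laid * (1 - prevalence * se_corr)^n_corr``.
    With ``herd_size`` the infested count is fixed at
    ``round(prevalence * herd_size)`` and animals are drawn without
    replacement (laid-down first, then corridor), summing the miss
    probability over the hypergeometric allocation of infested animals.
    """
    if sample.herd_size is None:
        p_miss = ((1 - sample.prevalence * sample.se_laid)
                  ** sample.n_laid_down
                  * (1 - sample.prevalence * sample.se_corridor)
                  ** sample.n_corridor)
        return 1.0 - p_miss

    n_herd = sample.herd_size
    n_inf = int(round(sample.prevalence * n_herd))
    kl = np.arange(min(sample.n_laid_down, n_inf) + 1)
    pl = stats.hypergeom.pmf(kl, n_herd, n_inf, sample.n_laid_down)
    p_miss = 0.0
    for k_laid, p_k in zip(kl, pl):
        if p_k == 0.0:
            continue
        rem_herd = n_herd - sample.n_laid_down
        rem_inf = n_inf - k_laid
        if sample.n_corridor == 0:
            miss_c = 1.0
        else:
            kc = np.arange(min(sample.n_corridor, rem_inf) + 1)
            pc = stats.hypergeom.pmf(kc, rem_herd, rem_inf,
                                     sample.n_corridor)
            miss_c = (pc * (1 - sample.se_corridor) ** kc).sum()
        p_miss += p_k * (1 - sample.se_laid) ** k_laid * miss_c
    return float(1.0 - p_miss)


def classify_detection(p: float, threshold: float = 0.7) -> str:
    """``"high"`` iff the detection probability strictly exceeds the
    threshold, else ``"low"``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return "high" if p > threshold else "low"
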