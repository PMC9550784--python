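"""Cascade activation calls from pairwise STR similarity and a noise floor.

A candidate cascade (e.g. Src-Raf1-MEK1-ERK1) is called *activated* when

* every consecutive edge — for branched steps such as ``MKK4|MKK3``, every
  listed branch edge — has similar STRs under the 2-of-3 rule, and
* every step's EAP STR exceeds the noise floor.

The noise floor is the maximal STR measured on antibody-free control spots
processed through the same duration/rate pipeline; steps whose rate does not
rise above what pure measurement noise produces are not considered
activated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import PosteriorSummary, SimilarityAssessment

#: fallback noise floor (1/min) when no negative-control spots are available
DEFAULT_NOISE_FLOOR = 0.10


@dataclass(frozen=True)
class CascadeSpec:
    """Ordered candidate cascade; a step may list alternatives separated by
    ``|`` (e.g. ``("ASK1", "MKK4|MKK3", "JNK")``)."""

    name: str
    steps: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        if len(self.steps) < 2:
            raise ValueError(f"cascade {self.name!r} needs at least 2 steps")

    @property
    def step_molecules(self) -> list[str]:
        out: list[str] = []
        for step in self.steps:
            out.extend(step.split("|"))
        return out

    @property
    def edges(self) -> list[tuple[str, str]]:
        """All consecutive branch edges."""
        out = []
        for up, down in zip(self.steps[:-1], self.steps[1:]):
            for u in up.split("|"):
                for d in down.split("|"):
                    out.append((u, d))
        return out


@dataclass(frozen=True)
class CascadeCall:
    name: str
    activated: bool
    failing_edges: tuple[tuple[str, str], ...]
    below_floor: tuple[str, ...]
    noise_floor: float


def noise_floor(negctrl_strs) -> float:
    """Maximal STR of the negative-control spots (1/min).

    An empty input is a configuration error (supply a manual floor instead);
    controls that never rise above baseline yield a floor of 0 with a
    warning.
    """
    vals = np.asarray(list(negctrl_strs), dtype=float)
    if vals.size == 0:
        raise ValueError(
            "no negative-control STR values; supply a manual noise floor"
        )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or vals.max() <= 0:
        warnings.warn("no measurable noise STR; floor set to 0", stacklevel=2)
        return 0.0
    return float(vals.max())


def assess_cascade(
    spec: CascadeSpec,
    posteriors: dict[str, PosteriorSummary],
    assessments: dict[tuple[str, str], SimilarityAssessment],
    floor: float = DEFAULT_NOISE_FLOOR,
) -> CascadeCall:
    """Decide activation of one candidate cascade.

    ``assessments`` maps ordered (upstream, downstream) pairs to verdicts;
    the reversed key is accepted as a fallback since similarity is a
    property of the pair.
    """
    failing = []
    for edge in spec.edges:
        a = assessments.get(edge) or assessments.get((edge[1], edge[0]))
        if a is None:
            raise KeyError(f"cascade {spec.name!r}: no similarity assessment for edge {edge}")
        if not a.similar:
            failing.append(edge)
    below = []
    for mol in spec.step_molecules:
        if mol not in posteriors:
            raise KeyError(f"cascade {spec.name!r}: no posterior for step {mol!r}")
        if posteriors[mol].eap_mu <= floor:
            below.append(mol)
    return CascadeCall(
        name=spec.name,
        activated=not failing and not below,
        failing_edges=tuple(failing),
        below_floor=tuple(below),
        noise_floor=float(floor),
    )
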