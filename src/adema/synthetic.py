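"""Synthetic cohorts and reference fixtures.

The generator emulates the kind of data the method targets: small two-class
cohorts of continuous positive concentrations, with class-dependent mean
shifts (in population-SD units) on chosen metabolites and Gaussian noise. It
makes no attempt to model real metabolomics error structure — its role is to
realize controllable class separations so every pipeline stage is testable
without external data.

Also provided: the 13-metabolite fatty-acid network (the de novo lipogenesis
chain plus the two essential fatty-acid elongation chains) used with the
blood cohorts, and the minimal two-metabolite worked example with one sample
per class whose documented outcome (variable: up/up, control: down/down)
serves as a regression anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .information import CONTROL, VARIABLE
from .network import MetabolicNetwork, parse_network
from .subsets import MetaboliteSubset

__all__ = ["SyntheticSpec", "generate_cohort", "dnl_network", "figure_example"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class cohort.

    shifted maps metabolite index -> shift in units of ``noise_sd`` applied to
    the variable class. Defaults mirror a small rodent cohort: 9 control vs
    7 variable samples, 13 metabolites, concentrations around 100 with 10%
    noise.
    """

    n_control: int = 9
    n_variable: int = 7
    n_metabolites: int = 13
    shifted: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 10.0
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_variable < 1:
            raise ValueError("each class needs at least one sample")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for j, s in self.shifted.items():
            if not (0 <= j < self.n_metabolites):
                raise ValueError(f"shifted index {j} out of range")
            if not np.isfinite(s):
                raise ValueError("shifts must be finite")


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw a cohort from the spec; a pure function of the spec (fixed seed
    gives a bit-identical cohort). Concentrations are truncated at zero."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_variable
    values = rng.normal(spec.baseline_mean, spec.noise_sd, size=(n, spec.n_metabolites))
    for j, shift in spec.shifted.items():
        values[spec.n_control :, j] += shift * spec.noise_sd
    values = np.clip(values, 0.0, None)
    labels = np.array([CONTROL] * spec.n_control + [VARIABLE] * spec.n_variable)
    return Cohort(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        metabolite_ids=[f"m{j + 1}" for j in range(spec.n_metabolites)],
        values=values,
        labels=labels,
    )


_DNL_REACTIONS = """\
# Fatty-acid network: de novo lipogenesis / elongation chain plus the two
# disconnected essential fatty-acid chains. One abstract reaction per arrow;
# boundary sources feed the three chain starts and sinks drain the products.
external: SRC_DNL SRC_OMEGA3 SRC_OMEGA6 SNK_PALMITOLEIC SNK_OLEIC SNK_DHA SNK_ARACHIDONIC
R01: SRC_DNL -> Decanoic
R02: Decanoic -> Dodecanoic
R03: Dodecanoic -> Tetradecanoic
R04: Tetradecanoic -> Palmitic
R05: Palmitic -> Palmitoleic
R06: Palmitoleic -> SNK_PALMITOLEIC
R07: Palmitic -> Stearic
R08: Stearic -> Oleic
R09: Oleic -> SNK_OLEIC
R10: SRC_OMEGA3 -> Linolenic
R11: Linolenic -> Eicosatetraenoic
R12: Eicosatetraenoic -> Eicosapentaenoic
R13: Eicosapentaenoic -> Docosahexaenoic
R14: Docosahexaenoic -> SNK_DHA
R15: SRC_OMEGA6 -> Linoleic
R16: Linoleic -> Arachidonic
R17: Arachidonic -> SNK_ARACHIDONIC
"""


def dnl_network() -> MetabolicNetwork:
    """The 13-metabolite fatty-acid network.

    Internal metabolites are the 13 measured fatty acids: the lipogenesis
    chain Decanoic -> Dodecanoic -> Tetradecanoic -> Palmitic, branching at
    Palmitic to Palmitoleic (sink) and via Stearic to Oleic (sink); the
    omega-3 chain Linolenic -> Eicosatetraenoic -> Eicosapentaenoic ->
    Docosahexaenoic; and the omega-6 pair Linoleic -> Arachidonic. This
    network has exactly four elementary flux modes (one per source-to-sink
    route).
    """
    return parse_network(_DNL_REACTIONS)


def dnl_network_text() -> str:
    """The reaction-list text of :func:`dnl_network` (for CLI fixtures)."""
    return _DNL_REACTIONS


def figure_example():
    """Minimal worked example: one sample per class, two metabolites, two bins.

    Returns ``(cohort, subsets, expected)`` where ``expected`` records the
    documented outcome: four bin combinations are enumerated, the variable
    class's expected bins are (2, 2) ("up, up") and the control class's are
    (1, 1) ("down, down"); M = 2, k = 2.
    """
    cohort = Cohort(
        sample_ids=["wt1", "cf1"],
        metabolite_ids=["met_a", "met_b"],
        values=np.array([[1.0, 1.0], [2.0, 2.0]]),
        labels=np.array([CONTROL, VARIABLE]),
    )
    subsets = [MetaboliteSubset(("met_a", "met_b"), source="toy")]
    expected = {
        "M": 2,
        "k": 2,
        "n_combinations": 4,
        "variable_bins": (2, 2),
        "control_bins": (1, 1),
    }
    return cohort, subsets, expected
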