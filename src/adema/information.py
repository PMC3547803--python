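"""Per-subset information statistics and class-specific expected levels.

For a subset ``Sub`` of metabolites binned into ``M`` levels, every assignment
of one bin per metabolite is a *bin combination* (substate) ``o``; there are
``M ** len(Sub)`` of them and all are used. With a binary class variable
``C`` (control vs. variable), the mutual information between the combination
variable and ``C`` decomposes over combinations,

    I(B_Sub; C) = sum_o mi_o,
    mi_o = sum_C p(C) p(o|C) log2( p(o|C) / p(o) ),

where ``p(o|C)`` is the mean, over samples of class ``C``, of the sample-wise
combination probability (a product of per-metabolite bin probabilities) and
``p(o)`` the mean over the whole population. By the log-sum inequality each
``mi_o >= 0``, and of the two class terms at most one exceeds the other
(when a combination is over-represented in one class it must be
under-represented in the other relative to the pooled frequency). Each
combination is therefore assigned to the class with the larger term; ties
(zero marginal information) go to control.

Per class, the expected bin of each metabolite in the subset is the
mi-weighted average of the combination's bin indices over the combinations
assigned to that class, rounded half away from zero. Across subsets, the
expected bins of a metabolite are combined as an average weighted by each
subset's total mutual information, rounded the same way. The difference
variable-minus-control per metabolite gives the predicted direction and
magnitude of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedCohort
from .subsets import MetaboliteSubset

__all__ = [
    "CONTROL",
    "VARIABLE",
    "enumerate_combinations",
    "combination_probability_individual",
    "combination_probability_population",
    "subset_mutual_information",
    "marginal_information",
    "classify_combination",
    "CombinationStat",
    "SubsetModel",
    "fit_subset_model",
    "expected_bins_from_weights",
    "round_half_away",
    "aggregate_expected_levels",
    "ExpectedLevels",
]

CONTROL = "control"
VARIABLE = "variable"


def round_half_away(x):
    """Round half away from zero (so 2.5 -> 3), elementwise."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def enumerate_combinations(M: int, d: int) -> np.ndarray:
    """All bin combinations for a subset of size ``d``: shape (M**d, d) of
    1-based bin indices, in lexicographic order (first metabolite most
    significant)."""
    grids = np.meshgrid(*[np.arange(1, M + 1)] * d, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _combination_probs(probs: np.ndarray) -> np.ndarray:
    """Sample-wise probabilities of every combination.

    probs : (n_samples, d, M) per-metabolite bin probabilities
    returns (n_samples, M**d), rows summing to 1, combination order matching
    :func:`enumerate_combinations`.
    """
    n, d, M = probs.shape
    out = np.ones((n, 1))
    for j in range(d):
        out = (out[:, :, None] * probs[:, j][:, None, :]).reshape(n, -1)
    return out


def _subset_probs(binned: BinnedCohort, metabolite_index: dict[str, int],
                  subset: MetaboliteSubset) -> np.ndarray:
    idx = [metabolite_index[m] for m in subset.members]
    return binned.probs[:, idx, :]


def combination_probability_individual(
    binned: BinnedCohort, sample: int, metabolite_index: dict[str, int],
    subset: MetaboliteSubset, o,
) -> float:
    """p_s(o): product over the subset of the sample's probability of each
    metabolite lying in the bin the combination assigns it."""
    o = np.asarray(o)
    p = 1.0
    for m, b in zip(subset.members, o):
        p *= binned.probs[sample, metabolite_index[m], b - 1]
    return p


def combination_probability_population(
    binned: BinnedCohort, metabolite_index: dict[str, int],
    subset: MetaboliteSubset, o, sample_mask=None,
) -> float:
    """p(o): arithmetic mean of the sample-wise probabilities over the
    (optionally masked) population."""
    probs = _subset_probs(binned, metabolite_index, subset)
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, bool)
        if not sample_mask.any():
            raise ValueError("sample filter selects no samples")
        probs = probs[sample_mask]
    per_sample = np.ones(probs.shape[0])
    for j, b in enumerate(np.asarray(o)):
        per_sample = per_sample * probs[:, j, b - 1]
    return float(per_sample.mean())


@dataclass(frozen=True)
class CombinationStat:
    """Information bookkeeping for one bin combination."""

    o: tuple[int, ...]
    p_o: float
    p_o_given_control: float
    p_o_given_variable: float
    term_control: float
    term_variable: float
    mi_o: float
    assigned_class: str


def classify_combination(stat: CombinationStat) -> str:
    """Assign a combination to the class whose information term dominates;
    a tie (zero marginal information) goes to control."""
    if stat.term_variable > stat.term_control:
        return VARIABLE
    return CONTROL


@dataclass
class SubsetModel:
    """Fitted information statistics for one metabolite subset.

    Attributes
    ----------
    subset : MetaboliteSubset
    M : int
    combos : ndarray (M**d, d) of 1-based bin indices
    mi : ndarray (M**d,) marginal information per combination (bits)
    term_control, term_variable : ndarray (M**d,)
    p_o, p_o_control, p_o_variable : ndarray (M**d,)
    assigned : ndarray (M**d,) of {"control", "variable"}
    I : float — subset mutual information, ``mi.sum()``
    expected_bins : dict class -> ndarray (d,) of expected bin per metabolite
    degenerate : dict class -> bool, True when the class had no informative
        combination and the midpoint fallback ``round((M+1)/2)`` was used
    """

    subset: MetaboliteSubset
    M: int
    combos: np.ndarray
    mi: np.ndarray
    term_control: np.ndarray
    term_variable: np.ndarray
    p_o: np.ndarray
    p_o_control: np.ndarray
    p_o_variable: np.ndarray
    assigned: np.ndarray
    I: float
    expected_bins: dict[str, np.ndarray] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)

    def stats(self) -> list[CombinationStat]:
        """Per-combination statistics as records."""
        return [
            CombinationStat(
                o=tuple(int(b) for b in self.combos[i]),
                p_o=float(self.p_o[i]),
                p_o_given_control=float(self.p_o_control[i]),
                p_o_given_variable=float(self.p_o_variable[i]),
                term_control=float(self.term_control[i]),
                term_variable=float(self.term_variable[i]),
                mi_o=float(self.mi[i]),
                assigned_class=str(self.assigned[i]),
            )
            for i in range(len(self.combos))
        ]


def _information_terms(p_cond: np.ndarray, p_all: np.ndarray, prior: float) -> np.ndarray:
    """prior * p(o|C) * log2(p(o|C) / p(o)) with the 0 log 0 := 0 convention."""
    out = np.zeros_like(p_cond)
    nz = p_cond > 0
    out[nz] = prior * p_cond[nz] * np.log2(p_cond[nz] / p_all[nz])
    return out


def fit_subset_model(
    binned: BinnedCohort,
    labels: np.ndarray,
    metabolite_index: dict[str, int],
    subset: MetaboliteSubset,
) -> SubsetModel:
    """Compute all combination statistics and class expectations for a subset.

    ``labels`` is an array over samples with values ``"control"`` /
    ``"variable"``; class priors are the empirical class frequencies.
    """
    labels = np.asarray(labels)
    ctrl = labels == CONTROL
    var = labels == VARIABLE
    if not ctrl.any() or not var.any():
        raise ValueError("both classes must be present to fit a subset model")
    probs = _subset_probs(binned, metabolite_index, subset)
    ps = _combination_probs(probs)  # (n, M**d)
    p_ctrl = ps[ctrl].mean(axis=0)
    p_var = ps[var].mean(axis=0)
    prior_ctrl = ctrl.mean()
    prior_var = var.mean()
    p_all = prior_ctrl * p_ctrl + prior_var * p_var
    term_c = _information_terms(p_ctrl, p_all, prior_ctrl)
    term_v = _information_terms(p_var, p_all, prior_var)
    mi = term_c + term_v
    M = binned.M
    combos = enumerate_combinations(M, len(subset))
    assigned = np.where(term_v > term_c, VARIABLE, CONTROL)
    model = SubsetModel(
        subset=subset, M=M, combos=combos, mi=mi,
        term_control=term_c, term_variable=term_v,
        p_o=p_all, p_o_control=p_ctrl, p_o_variable=p_var,
        assigned=assigned, I=float(mi.sum()),
    )
    for cls in (CONTROL, VARIABLE):
        mask = assigned == cls
        total = mi[mask].sum()
        if total <= 0:
            # no informative combination for this class: no predicted
            # deviation, fall back to the midpoint bin
            model.expected_bins[cls] = np.full(
                len(subset), round_half_away((M + 1) / 2), dtype=int
            )
            model.degenerate[cls] = True
        else:
            weights = mi[mask] / total
            model.expected_bins[cls] = expected_bins_from_weights(
                combos[mask], weights
            )
            model.degenerate[cls] = False
    return model


def expected_bins_from_weights(combos: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of bin indices per metabolite position, rounded half
    away from zero."""
    return round_half_away(weights @ combos)


def subset_mutual_information(
    binned: BinnedCohort, labels: np.ndarray,
    metabolite_index: dict[str, int], subset: MetaboliteSubset,
) -> float:
    """Plug-in mutual information I(B_Sub; C) in bits."""
    return fit_subset_model(binned, labels, metabolite_index, subset).I


def marginal_information(
    binned: BinnedCohort, labels: np.ndarray,
    metabolite_index: dict[str, int], subset: MetaboliteSubset, o,
) -> CombinationStat:
    """Statistics of a single combination (see :class:`CombinationStat`)."""
    model = fit_subset_model(binned, labels, metabolite_index, subset)
    o = tuple(int(b) for b in np.asarray(o))
    idx = int(np.flatnonzero((model.combos == o).all(axis=1))[0])
    return model.stats()[idx]


@dataclass
class ExpectedLevels:
    """Aggregated per-metabolite class-specific bins and their differences.

    ``delta = variable_bin - control_bin``; its sign is the predicted
    direction of change in the variable group, its magnitude the predicted
    strength. ``uncovered`` lists metabolites in no subset (no prediction).
    """

    metabolites: list[str]
    control_bins: dict[str, int]
    variable_bins: dict[str, int]
    uncovered: list[str] = field(default_factory=list)

    def delta(self, metabolite: str) -> int:
        return self.variable_bins[metabolite] - self.control_bins[metabolite]

    def direction(self, metabolite: str) -> str:
        d = self.delta(metabolite)
        return "increase" if d > 0 else "decrease" if d < 0 else "no-change"


def aggregate_expected_levels(
    models: list[SubsetModel], metabolites: list[str]
) -> ExpectedLevels:
    """Combine per-subset expected bins across all subsets containing each
    metabolite, weighting each subset by its share of the total mutual
    information those subsets carry; when every containing subset has zero
    information the subsets are weighted uniformly (the expectations are then
    the degenerate midpoints anyway)."""
    out = ExpectedLevels(metabolites=list(metabolites), control_bins={}, variable_bins={})
    for m in metabolites:
        containing = [mod for mod in models if m in mod.subset.members]
        if not containing:
            out.uncovered.append(m)
            continue
        total_I = sum(mod.I for mod in containing)
        if total_I > 0:
            weights = np.array([mod.I / total_I for mod in containing])
        else:
            weights = np.full(len(containing), 1.0 / len(containing))
        for cls, dest in ((CONTROL, out.control_bins), (VARIABLE, out.variable_bins)):
            bins = np.array([
                mod.expected_bins[cls][mod.subset.members.index(m)]
                for mod in containing
            ])
            dest[m] = int(round_half_away(float(weights @ bins)))
    return out
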