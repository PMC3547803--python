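"""Selection of related metabolite subsets.

The information engine scores combinations of binned levels within small
groups of metabolites; these groups should reflect genuine dependency.
Three strategies are provided:

* ``efm`` — all measured internal metabolites touched by the reactions of one
  elementary flux mode form a subset (flux-level dependency).
* ``neighborhood`` — for each measured internal metabolite, itself plus every
  measured metabolite sharing a reaction with it (topological closeness).
* ``random`` — seeded random groups, a baseline needing no network knowledge.

Oversize subsets are split into contiguous near-equal pieces no larger than
``max_sub``, since the combination space grows as ``M ** len(subset)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import FluxMode, MetabolicNetwork, enumerate_efms

__all__ = [
    "MetaboliteSubset",
    "subset_from_efm",
    "efm_subsets",
    "neighborhood_subsets",
    "random_subsets",
    "split_subset",
    "build_subsets",
    "read_subsets",
    "write_subsets",
]


@dataclass(frozen=True)
class MetaboliteSubset:
    """An ordered group of measured metabolite names plus a provenance tag."""

    members: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in subset {self.source!r}")

    def __len__(self) -> int:
        return len(self.members)


def _ordered_measured(network: MetabolicNetwork, measured) -> list[str]:
    measured = set(measured)
    return [m for m in network.internal_metabolites if m in measured]


def subset_from_efm(
    mode: FluxMode, network: MetabolicNetwork, measured
) -> MetaboliteSubset | None:
    """Measured internal metabolites that are a substrate or product of any
    reaction in the mode's support, in network row order.

    Returns None (dropped) when the mode touches no measured metabolite.
    """
    touched: set[str] = set()
    for rxn in network.reactions:
        if rxn.id in mode.support:
            touched.update(rxn.stoichiometry)
    members = [m for m in _ordered_measured(network, measured) if m in touched]
    if not members:
        return None
    tag = "efm:" + "+".join(sorted(mode.support))
    return MetaboliteSubset(tuple(members), source=tag)


def efm_subsets(
    network: MetabolicNetwork, measured, max_reactions: int = 32
) -> list[MetaboliteSubset]:
    """One subset per elementary flux mode (empty intersections dropped)."""
    out = []
    for mode in enumerate_efms(network, max_reactions=max_reactions):
        sub = subset_from_efm(mode, network, measured)
        if sub is not None:
            out.append(sub)
    return out


def neighborhood_subsets(network: MetabolicNetwork, measured) -> list[MetaboliteSubset]:
    """One subset per measured internal metabolite: the origin plus every
    measured metabolite sharing a reaction with it. Identical member sets are
    merged; order is deterministic (network row order within subsets, origin
    order across them)."""
    order = _ordered_measured(network, measured)
    internal = set(network.internal_metabolites)
    out: list[MetaboliteSubset] = []
    seen: set[tuple[str, ...]] = set()
    for origin in order:
        hood = {origin}
        for rxn in network.reactions:
            if origin in rxn.stoichiometry:
                hood.update(m for m in rxn.stoichiometry if m in internal)
        members = tuple(m for m in order if m in hood)
        if members not in seen:
            seen.add(members)
            out.append(MetaboliteSubset(members, source=f"hood:{origin}"))
    return out


def random_subsets(
    measured, count: int, max_sub: int, seed: int
) -> list[MetaboliteSubset]:
    """``count`` seeded random subsets, each of size uniform in [2, max_sub]
    (capped at the number of measured metabolites), members drawn without
    replacement within each subset."""
    if count < 1:
        raise ValueError("count must be >= 1")
    measured = list(measured)
    rng = np.random.default_rng(seed)
    hi = min(max_sub, len(measured))
    lo = min(2, hi)
    out = []
    for idx in range(count):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(measured[i] for i in sorted(rng.choice(len(measured), size, replace=False)))
        out.append(MetaboliteSubset(members, source=f"random:{idx}"))
    return out


def split_subset(subset: MetaboliteSubset, max_sub: int) -> list[MetaboliteSubset]:
    """Split an oversize subset into ``ceil(n / max_sub)`` contiguous,
    non-overlapping, near-equal pieces, each of size <= ``max_sub``."""
    n = len(subset)
    if n <= max_sub:
        return [subset]
    n_pieces = -(-n // max_sub)
    base, rem = divmod(n, n_pieces)
    sizes = [base + 1] * rem + [base] * (n_pieces - rem)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [
        MetaboliteSubset(
            subset.members[a:b], source=f"{subset.source}/part{i + 1}"
        )
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def build_subsets(
    strategy: str,
    measured,
    network: MetabolicNetwork | None = None,
    max_sub: int = 8,
    n_random_subsets: int | None = None,
    seed: int = 0,
    max_reactions: int = 32,
) -> list[MetaboliteSubset]:
    """Dispatch on strategy and apply the max-size splitting rule."""
    if strategy in ("efm", "neighborhood") and network is None:
        raise ValueError(f"strategy {strategy!r} requires a metabolic network")
    if strategy == "efm":
        raw = efm_subsets(network, measured, max_reactions=max_reactions)
    elif strategy == "neighborhood":
        raw = neighborhood_subsets(network, measured)
    elif strategy == "random":
        if n_random_subsets is None:
            raise ValueError("random strategy requires n_random_subsets")
        raw = random_subsets(measured, n_random_subsets, max_sub, seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    out: list[MetaboliteSubset] = []
    for sub in raw:
        out.extend(split_subset(sub, max_sub))
    return out


def read_subsets(path: str | Path) -> list[MetaboliteSubset]:
    """Read subsets from a file, one subset per line, tab-separated names."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(MetaboliteSubset(tuple(line.split("\t")), source=f"file:{i}"))
    return out


def write_subsets(subsets: list[MetaboliteSubset], path: str | Path) -> None:
    Path(path).write_text(
        "".join("\t".join(s.members) + "\n" for s in subsets)
    )
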