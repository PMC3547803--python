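"""Metabolic networks and elementary flux mode (EFM) enumeration.

A network is a list of reactions over internal (balanced at steady state) and
external (boundary source/sink) metabolites. An elementary flux mode is a
minimal set of reactions that can carry a steady-state flux: ``S v = 0`` over
the internal metabolites, with ``v >= 0`` on irreversible reactions, and no
proper subset of its active reactions admitting such a flux.

Enumeration uses the classical Schuster-style tableau: reversible reactions
are split into irreversible forward/backward pairs, metabolite constraints are
imposed one at a time by combining positive- and negative-balance modes, and
non-elementary combinations are discarded by the pairwise support-minimality
test. Arithmetic is exact (:class:`fractions.Fraction`), so ``S v = 0`` holds
identically, not merely to a tolerance. This is intended for the modest
curated networks this method operates on, not genome scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "FluxMode",
    "parse_network",
    "read_network",
    "enumerate_efms",
]


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]  # metabolite -> signed coefficient
    reversible: bool = False


@dataclass
class MetabolicNetwork:
    """Reaction list plus the internal/external metabolite partition.

    ``internal_metabolites`` are balanced at steady state and are the only ones
    eligible for metabolite subsets; ``external_metabolites`` mark the entry
    and exit points of the network.
    """

    reactions: list[Reaction]
    external_metabolites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction ID {rxn.id!r}")
            seen.add(rxn.id)
            if not rxn.stoichiometry:
                raise ValueError(f"reaction {rxn.id!r} touches no metabolite")
        ext = set(self.external_metabolites)
        used = {m for rxn in self.reactions for m in rxn.stoichiometry}
        unknown = ext - used
        if unknown:
            raise ValueError(
                f"external metabolite(s) not used by any reaction: {sorted(unknown)}"
            )
        # internal metabolites in first-appearance (file) order
        order: list[str] = []
        for rxn in self.reactions:
            for m in rxn.stoichiometry:
                if m not in ext and m not in order:
                    order.append(m)
        self.internal_metabolites: list[str] = order

    def stoichiometric_matrix(self) -> list[list[Fraction]]:
        """Rows = internal metabolites (in order), columns = reactions."""
        idx = {m: i for i, m in enumerate(self.internal_metabolites)}
        S = [[Fraction(0)] * len(self.reactions) for _ in self.internal_metabolites]
        for j, rxn in enumerate(self.reactions):
            for m, c in rxn.stoichiometry.items():
                if m in idx:
                    S[idx[m]][j] = c
        return S


@dataclass(frozen=True)
class FluxMode:
    """An elementary mode: per-reaction net coefficients and its support.

    Coefficients are normalized so the smallest nonzero magnitude is 1; the
    support is the set of active reaction ids.
    """

    coefficients: tuple[Fraction, ...]
    support: frozenset[str]


_ARROW = re.compile(r"(<->|->)")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?([A-Za-z_][\w\-:+()\[\]]*)$")


def _parse_side(side: str, line: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM.match(term.strip())
        if m is None:
            raise ValueError(f"cannot parse metabolite term {term.strip()!r} in {line!r}")
        coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
        name = m.group(2)
        out[name] = out.get(name, Fraction(0)) + coeff
    return out


def parse_network(text: str) -> MetabolicNetwork:
    """Parse a plain-text reaction list.

    One reaction per line, ``ID: a M1 + b M2 -> c M3`` (``<->`` for
    reversible); a line ``external: M1 M2 ...`` declares the boundary
    metabolites. ``#`` starts a comment.
    """
    reactions: list[Reaction] = []
    external: list[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("external:"):
            external.extend(line.split(":", 1)[1].split())
            continue
        if ":" not in line:
            raise ValueError(f"missing 'ID:' prefix in line {line!r}")
        rid, body = line.split(":", 1)
        parts = _ARROW.split(body)
        if len(parts) != 3:
            raise ValueError(f"malformed or missing arrow in line {line!r}")
        lhs, arrow, rhs = parts
        stoich = {m: -c for m, c in _parse_side(lhs, line).items()}
        for m, c in _parse_side(rhs, line).items():
            stoich[m] = stoich.get(m, Fraction(0)) + c
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reactions.append(Reaction(rid.strip(), stoich, reversible=(arrow == "<->")))
    return MetabolicNetwork(reactions, external)


def read_network(path: str | Path) -> MetabolicNetwork:
    """Read a reaction-list file (see :func:`parse_network` for the format)."""
    return parse_network(Path(path).read_text())


def _support(v: list[Fraction]) -> frozenset[int]:
    return frozenset(i for i, x in enumerate(v) if x != 0)


def enumerate_efms(network: MetabolicNetwork, max_reactions: int = 32) -> list[FluxMode]:
    """Enumerate all elementary flux modes of a network.

    Returns the complete, duplicate-free mode set (unique up to scaling),
    deterministically ordered by support size then reaction ids. Fully
    reversible modes are reported once, in the orientation in which the
    tableau produces them first.

    Raises
    ------
    ValueError
        If the reaction count after splitting reversible reactions exceeds
        ``max_reactions`` — precompute subsets externally for such networks.
    """
    # columns after splitting reversible reactions into forward/backward
    cols: list[tuple[int, int]] = []  # (reaction index, direction +1/-1)
    for j, rxn in enumerate(network.reactions):
        cols.append((j, +1))
        if rxn.reversible:
            cols.append((j, -1))
    if len(cols) > max_reactions:
        raise ValueError(
            f"{len(cols)} reactions after reversibility splitting exceeds the "
            f"enumeration cap of {max_reactions}; supply precomputed subsets instead"
        )
    S = network.stoichiometric_matrix()
    Ssplit = [[S[i][j] * d for (j, d) in cols] for i in range(len(S))]

    nc = len(cols)
    modes: list[list[Fraction]] = [
        [Fraction(1) if c == r else Fraction(0) for c in range(nc)] for r in range(nc)
    ]
    for row in Ssplit:
        dots = [sum(r * v for r, v in zip(row, m)) for m in modes]
        zeros = [m for m, d in zip(modes, dots) if d == 0]
        pos = [(m, d) for m, d in zip(modes, dots) if d > 0]
        neg = [(m, d) for m, d in zip(modes, dots) if d < 0]
        candidates = list(zeros)
        for p, a in pos:
            for n, b in neg:
                # a > 0, b < 0: S_row . (a*n + (-b)*p) = 0
                candidates.append([a * nj + (-b) * pj for pj, nj in zip(p, n)])
        # pairwise support-minimality filter (elementarity test)
        supports = [_support(m) for m in candidates]
        keep: list[list[Fraction]] = []
        seen: set[frozenset[int]] = set()
        for ci, (cand, sup) in enumerate(zip(candidates, supports)):
            if not sup or sup in seen:
                continue
            if any(sj < sup for sj in supports):
                continue
            seen.add(sup)
            keep.append(cand)
        modes = keep

    out: list[FluxMode] = []
    seen_net: set[tuple[frozenset[str], tuple[Fraction, ...]]] = set()
    for m in modes:
        net = [Fraction(0)] * len(network.reactions)
        for c, (j, d) in enumerate(cols):
            net[j] += m[c] * d
        support = frozenset(
            network.reactions[j].id for j, x in enumerate(net) if x != 0
        )
        if not support:
            continue  # futile two-cycle of a split reversible reaction
        scale = min(abs(x) for x in net if x != 0)
        net = [x / scale for x in net]
        # canonical orientation so a fully reversible mode appears once
        canon = tuple(net)
        flipped = tuple(-x for x in net)
        key = (support, min(canon, flipped))
        if key in seen_net:
            continue
        seen_net.add(key)
        out.append(FluxMode(coefficients=canon, support=support))
    out.sort(key=lambda fm: (len(fm.support), sorted(fm.support)))
    return out
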