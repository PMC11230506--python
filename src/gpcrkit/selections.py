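"""A small atom-selection mini-language.

Clauses joined with ``and``; each clause is a keyword followed by one or more
values (space- or comma-separated):

    chain A
    resid 380-394            (ranges and comma lists: 1-5,8,10-12)
    resname TYR PHE
    name CA CB
    element C N
    hetero / protein         (flags, no values)

Example: ``"chain A and resid 102 and name CA"``.  Resolution against a
`StructureModel` is deterministic and preserves file order; resolving to an
empty set raises at use time, naming the expression.
"""

from __future__ import annotations

import numpy as np

from .structure import StructureModel

__all__ = ["AtomSelection", "SelectionError", "resolve"]


class SelectionError(ValueError):
    pass


def _parse_int_list(tokens: list[str]) -> list[tuple[int, int]]:
    ranges = []
    for tok in ",".join(tokens).split(","):
        tok = tok.strip()
        if not tok:
            continue
        if "-" in tok[1:]:  # allow negative lower bound
            cut = tok.index("-", 1)
            ranges.append((int(tok[:cut]), int(tok[cut + 1:])))
        else:
            ranges.append((int(tok), int(tok)))
    return ranges


class AtomSelection:
    """A parsed selection expression; resolve with :meth:`resolve`."""

    _KEYWORDS = ("chain", "resid", "resname", "name", "element", "hetero", "protein")

    def __init__(self, expression: str):
        self.expression = expression
        self._clauses = []
        for raw in expression.split(" and "):
            parts = raw.strip().split()
            if not parts:
                continue
            key = parts[0].lower()
            if key not in self._KEYWORDS:
                raise SelectionError(f"unknown selection keyword '{key}' in '{expression}'")
            values = [p for tok in parts[1:] for p in tok.split(",") if p]
            if key in ("hetero", "protein"):
                if values:
                    raise SelectionError(f"'{key}' takes no values")
                self._clauses.append((key, None))
            elif key == "resid":
                self._clauses.append((key, _parse_int_list(parts[1:])))
            else:
                if not values:
                    raise SelectionError(f"'{key}' needs at least one value")
                self._clauses.append((key, values))
        if not self._clauses:
            raise SelectionError(f"empty selection expression '{expression}'")

    def mask(self, model: StructureModel) -> np.ndarray:
        m = np.ones(model.n_atoms, dtype=bool)
        for key, values in self._clauses:
            if key == "chain":
                m &= np.isin(model.chain.astype(str), values)
            elif key == "resname":
                m &= np.isin(model.resname.astype(str), values)
            elif key == "name":
                m &= np.isin(model.name.astype(str), values)
            elif key == "element":
                m &= np.isin(model.element.astype(str), [v.capitalize() for v in values])
            elif key == "resid":
                sub = np.zeros(model.n_atoms, dtype=bool)
                for lo, hi in values:
                    sub |= (model.resid >= lo) & (model.resid <= hi)
                m &= sub
            elif key == "hetero":
                m &= model.hetero
            elif key == "protein":
                m &= ~model.hetero
        return m

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Atom indices matching the expression, in file order."""
        idx = np.flatnonzero(self.mask(model))
        if idx.size == 0:
            raise SelectionError(f"selection '{self.expression}' matched no atoms")
        return idx

    def __repr__(self):
        return f"AtomSelection({self.expression!r})"


def resolve(model: StructureModel, selection) -> np.ndarray:
    """Resolve a selection given as expression string, AtomSelection or indices."""
    if isinstance(selection, AtomSelection):
        return selection.resolve(model)
    if isinstance(selection, str):
        return AtomSelection(selection).resolve(model)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty index selection")
    return idx
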