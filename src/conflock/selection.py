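"""Atom-selection mini-language.

Grammar (lowest to highest precedence)::

    expr      := term ( "or" term )*
    term      := factor ( "and" factor )*
    factor    := "not" factor | "(" expr ")" | primitive
    primitive := "calpha" | "backbone" | "ligand" | "water" | "protein"
               | "all" | "resid" RANGE ( "," RANGE )*
    RANGE     := INT | INT "-" INT          (inclusive)

``calpha`` means protein alpha-carbons: the alpha_carbon flag minus any atom
flagged ligand or water.  ``resid`` matches residue numbers verbatim from the
topology (1-based, no renumbering), so literature residue labels such as
Glu451 are addressable directly as ``resid 451``.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import EmptySelectionError, SelectionError
from .io import Topology

_TOKEN = re.compile(r"\s*(\(|\)|,|[A-Za-z_]+|\d+\s*-\s*\d+|\d+)")

_KEYWORDS = {"calpha", "backbone", "ligand", "water", "protein", "all"}


class SelectionMask:
    """Strictly increasing, non-empty atom indices into a topology."""

    def __init__(self, indices) -> None:
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if idx.size == 0:
            raise EmptySelectionError("selection matched no atoms")
        if idx[0] < 0:
            raise SelectionError("negative atom index")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self):
        return iter(self.indices)

    def __eq__(self, other) -> bool:
        return isinstance(other, SelectionMask) and np.array_equal(self.indices, other.indices)

    def __repr__(self) -> str:
        return f"SelectionMask({self.indices.tolist()!r})"


def _tokenize(expression: str):
    tokens, pos = [], 0
    while pos < len(expression):
        if expression[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(expression, pos)
        if not m:
            raise SelectionError(f"cannot tokenize selection at position {pos}: {expression[pos:]!r}")
        tokens.append((m.group(1), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, topology: Topology):
        self.tokens = tokens
        self.i = 0
        self.top = topology

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        if self.i >= len(self.tokens):
            raise SelectionError("unexpected end of selection expression")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(f"unexpected token {tok!r} at position {pos}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            closing, pos = self.next()
            if closing != ")":
                raise SelectionError(f"expected ')' at position {pos}")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok, pos = self.next()
        f = self.top.flags
        if tok == "calpha":
            return f["alpha_carbon"] & ~f["ligand"] & ~f["water"]
        if tok == "backbone":
            return f["backbone"] & ~f["ligand"] & ~f["water"]
        if tok == "ligand":
            return f["ligand"].copy()
        if tok == "water":
            return f["water"].copy()
        if tok == "protein":
            return ~f["ligand"] & ~f["water"]
        if tok == "all":
            return np.ones(self.top.n_atoms, dtype=bool)
        if tok == "resid":
            mask = np.zeros(self.top.n_atoms, dtype=bool)
            while True:
                rng, rpos = self.next()
                if "-" in rng:
                    lo_s, hi_s = rng.split("-")
                    lo, hi = int(lo_s), int(hi_s)
                elif rng.isdigit():
                    lo = hi = int(rng)
                else:
                    raise SelectionError(f"expected residue number at position {rpos}, got {rng!r}")
                if hi < lo:
                    raise SelectionError(f"empty residue range {lo}-{hi} at position {rpos}")
                mask |= (self.top.resids >= lo) & (self.top.resids <= hi)
                if self.peek() == ",":
                    self.next()
                else:
                    break
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r} at position {pos}")


def select(topology: Topology, expression: str) -> SelectionMask:
    """Evaluate a selection expression against a topology.

    Raises :class:`SelectionError` with the offending position on a grammar
    error and :class:`EmptySelectionError` when nothing matches.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return SelectionMask(np.flatnonzero(mask))
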