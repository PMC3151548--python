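"""Path-style atom selection language.

Grammar (a minimal reconstruction; extensions beyond it are flagged in the
docs): ``/SEGID-SPEC/RESID-SPEC/ATOM-SPEC`` where each field is a
comma-separated list of tokens:

* ``*``            wildcard (matches everything in that field)
* ``@(a-b)``       inclusive numeric residue range; both the ASCII hyphen
                   and the typographic en-dash are accepted
* an integer       a residue number (RESID field)
* a bare word      a segment ID, residue name, or atom name depending on
                   the field

Example: ``/*/@(1-10)/*`` selects all atoms of residues 1-10 in every
segment; ``/*/*/CA`` selects every alpha-carbon.
"""

from __future__ import annotations

import re

from .core import Selection, Structure
from .errors import SelectionError

_RANGE_RE = re.compile(r"^@\((\d+)[–—-](\d+)\)$")


def _parse_field(field: str, where: str):
    """Compile one field into a list of token predicates-as-specs."""
    if field == "":
        raise SelectionError(f"empty {where} field in selection")
    tokens = []
    for tok in field.split(","):
        tok = tok.strip()
        if tok == "":
            raise SelectionError(f"empty token in {where} field")
        if tok == "*":
            tokens.append(("any",))
        elif tok.startswith("@"):
            m = _RANGE_RE.match(tok)
            if not m:
                raise SelectionError(
                    f"malformed range token {tok!r} in {where} field "
                    f"(expected @(a-b))")
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                lo, hi = hi, lo
            tokens.append(("range", lo, hi))
        elif re.fullmatch(r"-?\d+", tok):
            tokens.append(("number", int(tok)))
        else:
            tokens.append(("name", tok.upper()))
    return tokens


def parse_expression(expression: str):
    expr = expression.strip()
    if not expr.startswith("/"):
        raise SelectionError(
            f"selection must start with '/': failing token {expr.split('/')[0]!r}")
    parts = expr.split("/")
    # leading '' from the initial slash
    if len(parts) != 4:
        raise SelectionError(
            f"selection needs exactly three '/'-separated fields "
            f"(segment/residue/atom), got {len(parts) - 1} in {expression!r}")
    _, seg, res, atom = parts
    return (_parse_field(seg, "segment"),
            _parse_field(res, "residue"),
            _parse_field(atom, "atom"))


def _match(tokens, *, number=None, names=()) -> bool:
    for tok in tokens:
        kind = tok[0]
        if kind == "any":
            return True
        if kind == "range" and number is not None and tok[1] <= number <= tok[2]:
            return True
        if kind == "number" and number is not None and tok[1] == number:
            return True
        if kind == "name" and any(tok[1] == n.upper() for n in names):
            return True
    return False


def select(structure: Structure, expression: str) -> Selection:
    """Resolve a selection expression against a structure.

    Returns matching atom indices in structure order; an empty match is a
    valid (empty) Selection, while a syntax error raises SelectionError
    naming the failing token.
    """
    seg_toks, res_toks, atom_toks = parse_expression(expression)
    indices = []
    for i, a in enumerate(structure.atoms):
        if not _match(seg_toks, names=(a.segid, a.chain)):
            continue
        if not _match(res_toks, number=a.resid, names=(a.resname,)):
            continue
        if not _match(atom_toks, names=(a.name,)):
            continue
        indices.append(i)
    return Selection(expression, indices)
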