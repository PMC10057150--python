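"""Reading and writing AMBER frcmod parameter-modification files.

Two export dialects are supported because the fitted torsion library contains
periodicities that standard AMBER tooling does not expect:

``literal`` (default)
    The periodicity PN is written exactly as stored, including negative and
    non-integer values, each flagged with a trailing comment. Round-trips the
    library bit-exactly at the written precision and is the dialect the energy
    evaluator assumes.

``strict``
    PN is rounded to the nearest nonzero integer so stock AMBER programs can
    read the file; multi-term series use the standard negative-PN
    continuation-line convention. A :class:`~boronfit.errors.LossyExportWarning`
    is emitted for any term whose |n| moves by more than 0.5 in the rounding.

Numeric precision on write: 2/3 decimals for bonds, 2/2 for angles, 4 decimals
for V_n and gamma, 3 for n.
"""

from __future__ import annotations

import warnings

from .errors import FormatError, LossyExportWarning
from .params import (
    AngleParam,
    AtomTypeKey,
    BondParam,
    DihedralTermParam,
    ParameterSet,
)

_SECTIONS = ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON")


def _fmt_types(labels) -> str:
    return "-".join(lab.ljust(2) for lab in labels).rstrip()


def _parse_types(line: str, n: int):
    """Split the leading atom-type field of a parameter line.

    Tries the fixed-width AMBER layout (two characters per type, ``-``
    separators) first, then falls back to treating the first whitespace token
    as a compact ``a-b-c-d`` field.
    """
    width = 3 * n - 1
    labels = [s.strip() for s in line[:width].split("-")]
    if len(labels) == n and all(labels) and all(" " not in lab for lab in labels):
        return labels, line[width:]
    tok = line.split(None, 1)
    labels = tok[0].split("-")
    if len(labels) == n and all(labels):
        return labels, tok[1] if len(tok) > 1 else ""
    raise ValueError(f"cannot split {n} atom types from {line!r}")


def _leading_floats(text: str) -> list[float]:
    vals = []
    for tok in text.split():
        try:
            vals.append(float(tok))
        except ValueError:
            break
    return vals


def read_frcmod(path, dialect: str = "literal") -> ParameterSet:
    """Parse an frcmod file into a :class:`ParameterSet`.

    Any subset of the MASS/BOND/ANGLE/DIHE/IMPROPER/NONBON sections may be
    present; MASS and NONBON entries are skipped (the set carries bonded
    parameters only). In the ``strict`` dialect a negative DIHE periodicity is
    the multi-term continuation flag and |PN| is stored; in ``literal`` it is
    stored as written.
    """
    if dialect not in ("literal", "strict"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pset = ParameterSet()
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if lineno == 1 and stripped.upper() not in _SECTIONS:
                continue  # title line
            if not stripped:
                continue
            upper = stripped.upper()
            matched = next((s for s in _SECTIONS if upper.startswith(s)), None)
            if matched and len(stripped.split()) == 1:
                section = matched
                continue
            if section in (None, "MASS", "NONBON"):
                continue
            try:
                if section == "BOND":
                    labels, rest = _parse_types(line, 2)
                    kr, req = _leading_floats(rest)[:2]
                    pset.add_bond(BondParam(AtomTypeKey(tuple(labels)), kr, req))
                elif section == "ANGLE":
                    labels, rest = _parse_types(line, 3)
                    kt, te = _leading_floats(rest)[:2]
                    pset.add_angle(AngleParam(AtomTypeKey(tuple(labels)), kt, te))
                elif section == "DIHE":
                    labels, rest = _parse_types(line, 4)
                    vals = _leading_floats(rest)
                    if len(vals) < 4:
                        raise ValueError("need IDIVF PK PHASE PN")
                    div, v, g, n = vals[:4]
                    if dialect == "strict":
                        n = abs(n)
                    pset.add_dihedral(
                        DihedralTermParam(
                            AtomTypeKey(tuple(labels)), int(div), v, g, n
                        )
                    )
                elif section == "IMPROPER":
                    labels, rest = _parse_types(line, 4)
                    vals = _leading_floats(rest)
                    if len(vals) >= 4:  # tolerate an explicit IDIVF column
                        div, v, g, n = vals[:4]
                    elif len(vals) == 3:
                        div, (v, g, n) = 1, vals
                    else:
                        raise ValueError("need PK PHASE PN")
                    pset.add_dihedral(
                        DihedralTermParam(
                            AtomTypeKey(tuple(labels)), int(div), v, g, n,
                            is_improper=True,
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise FormatError(str(exc), path=path, line=lineno) from exc
    return pset


def _strict_pn(term: DihedralTermParam) -> int:
    pn = int(round(abs(term.n)))
    if pn == 0:
        pn = 1
    if abs(abs(term.n) - pn) > 0.5:
        warnings.warn(
            f"strict export rounds n={term.n:g} to {pn} for {term.key}",
            LossyExportWarning,
            stacklevel=3,
        )
    return pn


def write_frcmod(
    pset: ParameterSet,
    path,
    dialect: str = "literal",
    title: str = "boronate covalent-warhead parameters (boronfit)",
) -> None:
    if dialect not in ("literal", "strict"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = [title, "MASS", "", "BOND"]
    for p in pset.bonds.values():
        lines.append(f"{_fmt_types(p.key.labels):<8}{p.k_r:10.2f}{p.r_eq:10.3f}")
    lines += ["", "ANGLE"]
    for p in pset.angles.values():
        lines.append(
            f"{_fmt_types(p.key.labels):<11}{p.k_theta:10.2f}{p.theta_eq:10.2f}"
        )
    lines += ["", "DIHE"]
    for terms in pset.propers.values():
        for i, t in enumerate(terms):
            types = f"{_fmt_types(t.key.labels):<14}"
            if dialect == "literal":
                comment = ""
                if t.n <= 0 or t.n != int(t.n):
                    comment = "    ; nonstandard periodicity (literal dialect)"
                lines.append(
                    f"{types}{t.divider:>4}{t.v_n:12.4f}{t.gamma:12.4f}"
                    f"{t.n:10.3f}{comment}"
                )
            else:
                pn = _strict_pn(t)
                if i < len(terms) - 1:
                    pn = -pn  # continuation: more terms follow for this key
                lines.append(
                    f"{types}{t.divider:>4}{t.v_n:12.4f}{t.gamma:12.4f}{pn:10d}"
                )
    lines += ["", "IMPROPER"]
    for terms in pset.impropers.values():
        for t in terms:
            types = f"{_fmt_types(t.key.labels):<14}"
            if dialect == "literal":
                lines.append(
                    f"{types}{t.v_n:12.4f}{t.gamma:12.4f}{t.n:10.3f}"
                )
            else:
                lines.append(
                    f"{types}{t.v_n:12.4f}{t.gamma:12.4f}{_strict_pn(t):10d}"
                )
    lines += ["", "NONBON", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
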