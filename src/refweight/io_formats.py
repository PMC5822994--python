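"""Readers and writers for structure-factor and metadata files.

Supported inputs
----------------
``.fcf``
    SHELXL LIST 4 or LIST 8 output: a CIF data block with a ``_refln`` loop
    carrying Fc^2, Fo^2 (meas) and sigma(Fo^2).  Columns are matched by CIF
    tag name, never by position, so any column order parses identically.
    When an observed-status column is present, rows flagged unobserved
    (status other than ``o``) are excluded by default; ``keep_all=True``
    retains them.  Both dialects are otherwise treated identically.
``.fco``
    XD-style fixed-column table from a multipolar refinement: a free-form
    header followed by one row per reflection.  The default column order is
    ``h k l Fc^2 Fo^2 sigma(Fo^2)``; XD versions vary, so the order can be
    overridden.  Header termination rule: the data body starts at the first
    line whose tokens are all numeric, that has at least as many tokens as
    the column map, and whose h, k, l positions hold integers; every
    subsequent non-blank line must be a data row with the same token count.
    Sigmas are taken on the same scale convention as ``.fcf`` sigmas.
``.ins`` / ``.mas``
    SHELX instruction files (``CELL`` card: wavelength then six cell
    parameters; optional ``WGHT`` card) and XD master files (``CELL`` card:
    six cell parameters; optional ``WAVE`` card with the wavelength).
``.cif``
    Only the refined-parameter count ``_refine_ls_number_parameters``.

Numbers are parsed in free format; Fortran-style ``D`` exponents and CIF
parenthesised standard uncertainties (``1.234(5)``) are accepted.  All
values are kept on the file's native scale.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from gemmi import cif

from .cell import UnitCell
from .errors import FormatError, ParseError, ValidationError
from .reflections import ReflectionSet
from .weights import WeightingScheme

__all__ = [
    "read_fcf",
    "read_fco",
    "read_ins_metadata",
    "read_mas_metadata",
    "read_cif_nparams",
    "write_fcf",
]

_SU_RE = re.compile(r"\(\d+\)$")

# CIF tag aliases, SHELXL underscore dialect first.
_TAG_ALIASES = {
    "f_calc_sq": ("_refln_F_squared_calc", "_refln.F_squared_calc"),
    "f_obs_sq": ("_refln_F_squared_meas", "_refln.F_squared_meas"),
    "sigma_f_obs_sq": ("_refln_F_squared_sigma", "_refln.F_squared_sigma"),
    "h": ("_refln_index_h", "_refln.index_h"),
    "k": ("_refln_index_k", "_refln.index_k"),
    "l": ("_refln_index_l", "_refln.index_l"),
    "status": ("_refln_observed_status", "_refln.status"),
}


def _to_float(token: str, where: str) -> float:
    """Free-format float: D exponents and trailing '(su)' accepted."""
    text = _SU_RE.sub("", token.strip())
    try:
        return float(text.replace("D", "E").replace("d", "e"))
    except ValueError:
        raise ParseError(f"non-numeric field {token!r} at {where}") from None


def _to_int(token: str, where: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"non-integer field {token!r} at {where}") from None


def _find_loop(block: "cif.Block", field: str):
    for tag in _TAG_ALIASES[field]:
        col = block.find_loop(tag)
        if len(col) > 0:
            return tag, list(col)
    return None, None


def _block_value(block: "cif.Block", *tags: str) -> Optional[float]:
    for tag in tags:
        val = block.find_value(tag)
        if val is not None and val not in (".", "?"):
            return _to_float(val, f"tag {tag}")
    return None


def read_fcf(path, keep_all: bool = False) -> ReflectionSet:
    """Read a SHELXL LIST 4/8 ``.fcf`` file into a :class:`ReflectionSet`.

    Rows flagged unobserved by an observed-status column are dropped unless
    ``keep_all`` is true.  The unit cell and wavelength are captured when the
    corresponding CIF items are present.  Row order is preserved.
    """
    path = Path(path)
    try:
        doc = cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as CIF: {exc}") from None

    block = None
    for cand in doc:
        if _find_loop(cand, "f_obs_sq")[1] is not None:
            block = cand
            break
    if block is None:
        # fall back to the first block so missing-tag errors name the tag
        if len(doc) == 0:
            raise FormatError(f"{path}: no CIF data block found")
        block = doc[0]

    columns = {}
    for field in ("h", "k", "l", "f_calc_sq", "f_obs_sq", "sigma_f_obs_sq"):
        tag, values = _find_loop(block, field)
        if values is None:
            raise FormatError(
                f"{path}: required refln loop tag missing: {_TAG_ALIASES[field][0]}"
            )
        columns[field] = (tag, values)

    n = len(columns["f_obs_sq"][1])
    hkl = np.empty((n, 3), dtype=np.int64)
    for j, field in enumerate(("h", "k", "l")):
        tag, vals = columns[field]
        hkl[:, j] = [_to_int(v, f"tag {tag}, row {i + 1}") for i, v in enumerate(vals)]
    data = {}
    for field in ("f_calc_sq", "f_obs_sq", "sigma_f_obs_sq"):
        tag, vals = columns[field]
        data[field] = np.array(
            [_to_float(v, f"tag {tag}, row {i + 1}") for i, v in enumerate(vals)]
        )

    keep = np.ones(n, dtype=bool)
    _, status = _find_loop(block, "status")
    if status is not None and not keep_all:
        keep = np.array([s.strip() == "o" for s in status])
        if not keep.any():
            raise ValidationError(f"{path}: all rows flagged unobserved")

    bad = np.flatnonzero(data["sigma_f_obs_sq"][keep] <= 0)
    if bad.size:
        idx = [tuple(int(x) for x in hkl[keep][i]) for i in bad[:10]]
        raise ValidationError(f"{path}: sigma(Fo^2) <= 0 for reflections {idx}")

    cell = None
    lengths = [_block_value(block, f"_cell_length_{x}", f"_cell.length_{x}") for x in "abc"]
    angles = [
        _block_value(block, f"_cell_angle_{x}", f"_cell.angle_{x}")
        for x in ("alpha", "beta", "gamma")
    ]
    if all(v is not None for v in lengths + angles):
        cell = UnitCell(*lengths, *angles)
    wavelength = _block_value(
        block, "_diffrn_radiation_wavelength", "_diffrn_radiation.wavelength"
    )
    n_params = None
    np_val = block.find_value("_refine_ls_number_parameters")
    if np_val is not None and np_val not in (".", "?"):
        n_params = _to_int(np_val, "tag _refine_ls_number_parameters")

    return ReflectionSet(
        hkl=hkl[keep],
        f_obs_sq=data["f_obs_sq"][keep],
        sigma_f_obs_sq=data["sigma_f_obs_sq"][keep],
        f_calc_sq=data["f_calc_sq"][keep],
        cell=cell,
        wavelength=wavelength,
        n_params=n_params,
    )


_DEFAULT_FCO_COLUMNS = ("h", "k", "l", "f_calc_sq", "f_obs_sq", "sigma_f_obs_sq")


def read_fco(
    path,
    columns: Sequence[str] = _DEFAULT_FCO_COLUMNS,
) -> ReflectionSet:
    """Read an XD-style ``.fco`` structure-factor table.

    ``columns`` names the meaning of the leading data columns and must be a
    permutation of ``('h', 'k', 'l', 'f_calc_sq', 'f_obs_sq',
    'sigma_f_obs_sq')``; trailing extra columns (e.g. phases) are ignored
    but must be present consistently on every row.
    """
    path = Path(path)
    columns = tuple(columns)
    if sorted(columns) != sorted(_DEFAULT_FCO_COLUMNS):
        raise ValidationError(
            f"columns must be a permutation of {_DEFAULT_FCO_COLUMNS}, got {columns}"
        )
    idx_pos = [columns.index(x) for x in ("h", "k", "l")]

    lines = path.read_text().splitlines()
    rows = []
    n_fields = None
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            if n_fields is not None and rows:
                continue  # blank line inside/after body
            continue
        if n_fields is None:
            # still in the header: does this line start the data body?
            if len(tokens) < len(columns):
                continue
            try:
                for p in idx_pos:
                    int(tokens[p])
                for t in tokens:
                    float(t.replace("D", "E").replace("d", "e"))
            except ValueError:
                continue
            n_fields = len(tokens)
        if len(tokens) != n_fields:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_fields} fields, got {len(tokens)}"
            )
        rows.append((lineno, tokens))

    if not rows:
        raise ValidationError(f"{path}: no reflection data rows found")

    n = len(rows)
    hkl = np.empty((n, 3), dtype=np.int64)
    arrays = {f: np.empty(n) for f in ("f_calc_sq", "f_obs_sq", "sigma_f_obs_sq")}
    for i, (lineno, tokens) in enumerate(rows):
        for j, field in enumerate(columns):
            where = f"{path.name}, line {lineno}"
            if field in ("h", "k", "l"):
                hkl[i, "hkl".index(field)] = _to_int(tokens[j], where)
            else:
                arrays[field][i] = _to_float(tokens[j], where)

    return ReflectionSet(
        hkl=hkl,
        f_obs_sq=arrays["f_obs_sq"],
        sigma_f_obs_sq=arrays["sigma_f_obs_sq"],
        f_calc_sq=arrays["f_calc_sq"],
    )


def read_ins_metadata(path) -> Tuple[UnitCell, float, WeightingScheme]:
    """Extract cell, wavelength and the current weighting scheme from a
    SHELX ``.ins``/``.res`` instruction file.

    The ``CELL`` card carries the wavelength followed by the six cell
    parameters.  A ``WGHT`` card supplies 1-6 weight parameters in the order
    a, b, c, d, e, f; absent parameters take the scheme defaults
    (b = c = d = e = 0, f = 1/3), and an absent card returns the default
    scheme entirely.
    """
    path = Path(path)
    cell = None
    wavelength = None
    scheme = WeightingScheme()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].upper()
        if key == "CELL":
            if len(tokens) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: CELL card needs 7 values "
                    f"(wavelength + 6 cell parameters), got {len(tokens) - 1}"
                )
            where = f"{path.name}, line {lineno}"
            vals = [_to_float(t, where) for t in tokens[1:]]
            wavelength = vals[0]
            cell = UnitCell(*vals[1:])
        elif key == "WGHT":
            where = f"{path.name}, line {lineno}"
            vals = [_to_float(t, where) for t in tokens[1:7]]
            defaults = [0.1, 0.0, 0.0, 0.0, 0.0, 1.0 / 3.0]
            vals = vals + defaults[len(vals):]
            scheme = WeightingScheme(*vals)
    if cell is None:
        raise FormatError(f"{path}: no CELL card found")
    return cell, wavelength, scheme


def read_mas_metadata(path) -> Tuple[UnitCell, Optional[float]]:
    """Extract cell and wavelength from an XD ``.mas`` master file.

    Record dialect: a ``CELL`` record carries the six cell parameters
    (a b c alpha beta gamma); a ``WAVE`` record carries the wavelength.
    The wavelength record is optional.
    """
    path = Path(path)
    cell = None
    wavelength = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].upper()
        where = f"{path.name}, line {lineno}"
        if key == "CELL":
            if len(tokens) != 7:
                raise ParseError(
                    f"{path}: line {lineno}: CELL record needs 6 values, got {len(tokens) - 1}"
                )
            cell = UnitCell(*[_to_float(t, where) for t in tokens[1:]])
        elif key == "WAVE":
            if len(tokens) < 2:
                raise ParseError(f"{path}: line {lineno}: WAVE record needs a value")
            wavelength = _to_float(tokens[1], where)
    if cell is None:
        raise FormatError(f"{path}: no CELL record found")
    return cell, wavelength


def read_cif_nparams(path) -> int:
    """Read the refined-parameter count ``_refine_ls_number_parameters``."""
    path = Path(path)
    try:
        doc = cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as CIF: {exc}") from None
    for block in doc:
        val = block.find_value("_refine_ls_number_parameters")
        if val is not None and val not in (".", "?"):
            p = _to_int(val, "tag _refine_ls_number_parameters")
            if p < 1:
                raise ValidationError(f"{path}: parameter count must be >= 1, got {p}")
            return p
    raise FormatError(f"{path}: item _refine_ls_number_parameters not found")


def write_fcf(rs: ReflectionSet, path) -> None:
    """Write a ReflectionSet as a CIF refln loop readable by :func:`read_fcf`.

    Numbers are written with ``repr`` (shortest round-trip form), so
    ``read_fcf(write_fcf(rs))`` reproduces every numeric field exactly.
    """
    if len(rs) == 0:
        raise ValidationError("cannot write an empty reflection set")
    path = Path(path)
    out = ["data_refweight"]
    if rs.cell is not None:
        c = rs.cell
        out += [
            f"_cell_length_a {float(c.a)!r}",
            f"_cell_length_b {float(c.b)!r}",
            f"_cell_length_c {float(c.c)!r}",
            f"_cell_angle_alpha {float(c.alpha)!r}",
            f"_cell_angle_beta {float(c.beta)!r}",
            f"_cell_angle_gamma {float(c.gamma)!r}",
        ]
    if rs.wavelength is not None:
        out.append(f"_diffrn_radiation_wavelength {float(rs.wavelength)!r}")
    if rs.n_params is not None:
        out.append(f"_refine_ls_number_parameters {rs.n_params}")
    out += [
        "loop_",
        " _refln_index_h",
        " _refln_index_k",
        " _refln_index_l",
        " _refln_F_squared_calc",
        " _refln_F_squared_meas",
        " _refln_F_squared_sigma",
    ]
    for i in range(len(rs)):
        h, k, l = (int(x) for x in rs.hkl[i])
        out.append(
            f" {h} {k} {l} {float(rs.f_calc_sq[i])!r}"
            f" {float(rs.f_obs_sq[i])!r} {float(rs.sigma_f_obs_sq[i])!r}"
        )
    try:
        path.write_text("\n".join(out) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from None
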