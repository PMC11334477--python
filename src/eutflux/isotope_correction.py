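"""Natural-abundance correction of carbon isotopologue distributions (CIDs).

A measured mass-shift distribution of a metabolite fragment mixes the
biological 13C labeling pattern with naturally occurring heavy isotopes of
every atom and with the chemical impurity of the tracer.  In low-resolution
mode the expected measured vector is a linear transform of the true carbon
isotopologue distribution:

    measured = M @ true,

where column j of the correction matrix M is the convolution of (a) the
natural mass-shift distribution of all non-carbon atoms, (b) the natural 13C
binomial over the n - j biologically unlabeled carbons, and (c) the
tracer-purity binomial over the j labeled carbons, truncated at mass shift n.
Correction solves the inverse problem by non-negative least squares and
renormalizes, which is robust to measurement noise and to the truncation
making M slightly column-substochastic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

#: Natural isotope mass-shift distributions (index = mass shift in Da,
#: relative to the lightest isotope).  IUPAC representative abundances.
NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse 'C3H7NO2'-style elemental formulas into {element: count}."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("atom counts must be >= 0")
    return counts


@dataclass
class IsotopologueDistribution:
    """Fractions M0..Mn of molecules carrying 0..n heavy tracer carbons."""

    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1:
            raise ValueError("CID must be a vector")
        if np.any(self.fractions < -1e-12):
            raise ValueError("CID entries must be >= 0")
        total = self.fractions.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"CID must sum to 1 (got {total:.8f})")

    @property
    def n_carbon(self) -> int:
        return len(self.fractions) - 1

    def mean_enrichment(self) -> float:
        """Average fraction of labeled carbon, sum_j j*Mj / n."""
        j = np.arange(len(self.fractions))
        return float(np.dot(j, self.fractions) / self.n_carbon)


def _binomial(n: int, p: float) -> np.ndarray:
    """Mass-shift distribution of n independent atoms heavy with prob. p."""
    dist = np.array([1.0])
    atom = np.array([1.0 - p, p])
    for _ in range(n):
        dist = np.convolve(dist, atom)
    return dist


def _element_power(dist: tuple[float, ...], n: int) -> np.ndarray:
    out = np.array([1.0])
    d = np.asarray(dist, dtype=float)
    for _ in range(n):
        out = np.convolve(out, d)
    return out


def build_correction_matrix(
    formula: str | dict[str, int],
    *,
    tracer_purity: float = 1.0,
    abundances: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Correction matrix for a fragment with the given elemental formula.

    Column j is the measured mass-shift distribution expected from molecules
    whose biological labeling is exactly Mj, truncated at shift n (the carbon
    count).  Columns therefore sum to <= 1.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError("tracer purity must be in (0, 1]")
    counts = parse_formula(formula)
    n = counts.get("C", 0)
    if n < 1:
        raise ValueError("formula must contain at least one carbon")
    tables = dict(NATURAL_ABUNDANCES)
    if abundances:
        tables.update({k: tuple(v) for k, v in abundances.items()})
    missing = [e for e in counts if e not in tables]
    if missing:
        raise ValueError(f"no natural-abundance data for {missing}")

    non_carbon = np.array([1.0])
    for elem, cnt in counts.items():
        if elem == "C" or cnt == 0:
            continue
        non_carbon = np.convolve(non_carbon, _element_power(tables[elem], cnt))

    c_tab = tables["C"]
    p_c13 = c_tab[1] / (c_tab[0] + c_tab[1]) if len(c_tab) > 1 else 0.0
    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.convolve(non_carbon, _binomial(n - j, p_c13))
        col = np.convolve(col, _binomial(j, tracer_purity))
        matrix[:, j] = col[: n + 1]
    return matrix


def correct_cid(
    measured: IsotopologueDistribution | np.ndarray,
    matrix: np.ndarray,
) -> tuple[IsotopologueDistribution, float]:
    """Invert the natural-abundance convolution by NNLS.

    Returns the corrected CID (renormalized to sum 1) and its mean 13C
    enrichment.  Raises on an all-zero measurement or a dimension mismatch.
    """
    vec = (
        measured.fractions
        if isinstance(measured, IsotopologueDistribution)
        else np.asarray(measured, dtype=float)
    )
    if vec.shape[0] != matrix.shape[0]:
        raise ValueError(
            f"measured length {vec.shape[0]} does not match matrix {matrix.shape}"
        )
    if np.all(vec == 0):
        raise ValueError("measured CID is all zero")
    sol, _ = nnls(matrix, vec)
    total = sol.sum()
    if total <= 0:
        raise ValueError("NNLS produced an all-zero solution")
    corrected = IsotopologueDistribution(sol / total)
    return corrected, corrected.mean_enrichment()


def forward_convolve(
    true_cid: IsotopologueDistribution | np.ndarray,
    formula: str | dict[str, int],
    *,
    tracer_purity: float = 1.0,
    abundances: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Expected measured vector for a known true CID (matrix @ true)."""
    vec = (
        true_cid.fractions
        if isinstance(true_cid, IsotopologueDistribution)
        else np.asarray(true_cid, dtype=float)
    )
    m = build_correction_matrix(
        formula, tracer_purity=tracer_purity, abundances=abundances
    )
    return m @ vec
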