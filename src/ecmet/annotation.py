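"""Accurate-mass annotation of FIA-TOF ions against a reference compound list.

Flow-injection negative-mode data carry no chromatographic information, so
ions are matched to candidate compounds purely by mass-to-charge ratio:
every (ion, compound) pair whose measured m/z lies within an absolute Da
tolerance of the adduct-predicted m/z is reported as a putative annotation.
Ambiguity is retained, not resolved — one ion may hit several compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ReferenceMassList

PROTON_MASS = 1.007276  # Da

#: supported singly charged negative-mode adducts: name -> m/z shift from
#: the neutral monoisotopic mass. [M+F]- reflects the NH4F mobile-phase
#: additive sometimes used in FIA methods.
ADDUCTS: dict[str, float] = {
    "[M-H]-": -PROTON_MASS,
    "[M+F]-": +18.998403,
}


@dataclass(frozen=True)
class IonFeature:
    """A measured ion: opaque id plus m/z in negative mode."""

    ion_id: str
    mz: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ConfigurationError(f"ion {self.ion_id!r}: mz must be > 0")


def expected_mz(mass: float, adduct: str = "[M-H]-") -> float:
    """Predicted m/z of a neutral monoisotopic mass under a charge-1 adduct."""
    if mass <= 0:
        raise ConfigurationError(f"neutral mass must be > 0, got {mass}")
    if adduct not in ADDUCTS:
        raise ConfigurationError(
            f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        )
    return mass + ADDUCTS[adduct]


def annotate_ions(
    ions: list[IonFeature] | pd.DataFrame,
    ref: ReferenceMassList,
    tolerance: float = 0.001,
    adduct: str = "[M-H]-",
    ppm: bool = False,
) -> pd.DataFrame:
    """Match measured ions to reference compounds by accurate mass.

    Parameters
    ----------
    ions:
        List of :class:`IonFeature` or DataFrame with columns ion_id, mz.
    ref:
        Reference compound list with neutral monoisotopic masses.
    tolerance:
        Match window. Absolute Da by default (e.g. 0.001 = 1 mDa, the
        intracellular setting; 0.003 for supernatant data); parts-per-million
        of the expected m/z when ``ppm`` is true.
    adduct:
        Adduct used to convert neutral masses to expected m/z.

    Returns
    -------
    DataFrame with columns ion_id, compound_id, name, mz, expected_mz,
    delta_m (signed, measured - expected, Da), tolerance_used; sorted by
    (ion_id, \\|delta_m\\|). Every qualifying pair is reported.
    """
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be > 0")
    if isinstance(ions, pd.DataFrame):
        ions = [IonFeature(str(r.ion_id), float(r.mz)) for r in ions.itertuples()]

    t = ref.table
    exp = np.array([expected_mz(m, adduct) for m in t["monoisotopic_mass"].astype(float)])
    order = np.argsort(exp)
    exp_sorted = exp[order]
    tol_sorted = exp_sorted * tolerance * 1e-6 if ppm else np.full_like(exp_sorted, tolerance)

    rows = []
    for ion in ions:
        # widest possible window, then exact per-compound check (ppm windows vary)
        max_tol = tol_sorted.max() if len(tol_sorted) else 0.0
        lo = np.searchsorted(exp_sorted, ion.mz - max_tol, side="left")
        hi = np.searchsorted(exp_sorted, ion.mz + max_tol, side="right")
        for k in range(lo, hi):
            delta = ion.mz - exp_sorted[k]
            if abs(delta) <= tol_sorted[k]:
                idx = order[k]
                rows.append(
                    {
                        "ion_id": ion.ion_id,
                        "compound_id": t["compound_id"].iloc[idx],
                        "name": t["name"].iloc[idx],
                        "mz": ion.mz,
                        "expected_mz": exp_sorted[k],
                        "delta_m": delta,
                        "tolerance_used": tol_sorted[k],
                    }
                )
    hits = pd.DataFrame(
        rows,
        columns=[
            "ion_id", "compound_id", "name", "mz",
            "expected_mz", "delta_m", "tolerance_used",
        ],
    )
    if len(hits):
        hits = (
            hits.assign(_abs=hits["delta_m"].abs())
            .sort_values(["ion_id", "_abs"], kind="stable")
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
    return hits


def write_annotation(hits: pd.DataFrame, path: str) -> None:
    """Write an annotation table with delta_m in mDa, as used in reports."""
    out = hits[["ion_id", "compound_id", "name", "delta_m"]].copy()
    out["delta_m_mDa"] = out.pop("delta_m") * 1e3
    out.to_csv(path, sep="\t", index=False)
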