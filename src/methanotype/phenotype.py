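"""Per-cow derived phenotypes.

Persistent emitter classification (L/M/H tertiles consistent over all
periods), energy-corrected milk (ECM), methane intensities per kg DMI and
per kg ECM, acid-insoluble-ash (AIA) marker digestibility, and volatile
fatty acid summaries including the (acetate + butyrate)/propionate ratio.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "classify_emitters",
    "compute_ecm",
    "marker_digestibility",
    "vfa_summaries",
    "methane_intensity",
    "ECM_COEFFICIENTS",
]

#: Energy-corrected-milk coefficients: ECM(kg) = milk_kg *
#: (c_fat*fat + c_protein*protein + c_lactose*lactose + c_const) / denom
#: with fat/protein/lactose in g/kg.  The 3140 kJ/kg reference-energy
#: convention for 4 % fat milk.
ECM_COEFFICIENTS = {
    "fat": 38.3,
    "protein": 24.2,
    "lactose": 16.54,
    "const": 20.7,
    "denom": 3140.0,
}


def classify_emitters(
    period_emissions: pd.DataFrame, n_groups: int = 3
) -> pd.Series:
    """Classify cows as persistent low (L), high (H) or medium (M) emitters.

    ``period_emissions`` is a cow x period matrix of mean emission rates
    (g CH4/day).  Cows missing any period are excluded.  Within each period
    the remaining cows are split into tertiles of that period's emission
    (ties broken by each cow's overall mean); a cow in the bottom tertile in
    every period is L, in the top tertile in every period is H, all others M.
    Classification depends on ranks only, so it is invariant under any
    strictly monotone transform of the rates.
    """
    mat = period_emissions.astype(float)
    complete = mat.dropna(axis=0)
    if len(complete) < 3:
        raise ValueError("fewer than 3 cows with complete period data")

    overall = complete.mean(axis=1)
    labels = pd.Series("excluded", index=mat.index, name="emitter_group", dtype=object)
    n = len(complete)
    tertile_of = pd.DataFrame(index=complete.index, columns=complete.columns, dtype=int)
    sizes = [len(part) for part in np.array_split(np.arange(n), n_groups)]
    for period in complete.columns:
        order = sorted(
            complete.index, key=lambda cow: (complete.loc[cow, period], overall[cow])
        )
        pos = 0
        for tert, size in enumerate(sizes):
            for cow in order[pos : pos + size]:
                tertile_of.loc[cow, period] = tert
            pos += size
    for cow in complete.index:
        terts = set(tertile_of.loc[cow])
        if terts == {0}:
            labels[cow] = "L"
        elif terts == {n_groups - 1}:
            labels[cow] = "H"
        else:
            labels[cow] = "M"
    return labels


def compute_ecm(
    milk_kg: float,
    fat: float,
    protein: float,
    lactose: float,
    coefficients: Mapping[str, float] | None = None,
):
    """Energy-corrected milk yield, kg/day.

    ``fat``, ``protein`` and ``lactose`` are milk concentrations in g/kg.
    ECM standardises yield to a 4 %-fat reference energy content; the
    function is homogeneous of degree 1 in ``milk_kg``.  Inputs may be
    scalars or aligned arrays.
    """
    c = dict(ECM_COEFFICIENTS if coefficients is None else coefficients)
    milk_kg, fat, protein, lactose = (
        np.asarray(x, dtype=float) for x in (milk_kg, fat, protein, lactose)
    )
    if np.any(milk_kg < 0) or np.any(fat < 0) or np.any(protein < 0) or np.any(lactose < 0):
        raise ValueError("milk yield and composition must be non-negative")
    energy = c["fat"] * fat + c["protein"] * protein + c["lactose"] * lactose + c["const"]
    out = milk_kg * energy / c["denom"]
    return float(out) if out.ndim == 0 else out


def marker_digestibility(
    intake: Mapping[str, float], fecal_conc: Mapping[str, float]
) -> dict:
    """Apparent digestibility from the acid-insoluble-ash (AIA) marker.

    ``intake`` holds nutrient intakes in kg/day (including ``AIA``);
    ``fecal_conc`` fecal concentrations in g/kg DM (including ``AIA``).
    AIA is indigestible, so fecal DM output = AIA intake / fecal AIA
    concentration; each nutrient's apparent digestibility is
    (intake - fecal concentration x fecal DM) / intake, reported x1000 as
    g/kg.  Negative digestibilities are flagged, not clamped — they signal a
    marker-recovery failure.

    Returns a dict with ``fecal_dm_kg``, per-nutrient digestibilities in
    g/kg, and a ``flags`` list naming nutrients with negative values.
    """
    aia_in = float(intake["AIA"])
    aia_conc = float(fecal_conc["AIA"])
    if aia_conc <= 0:
        raise ValueError("fecal AIA concentration must be positive")
    if aia_in <= 0:
        raise ValueError("AIA intake must be positive")
    fecal_dm = aia_in / aia_conc * 1000.0  # kg/day

    out: dict = {"fecal_dm_kg": fecal_dm, "flags": []}
    for nutrient, mass_in in intake.items():
        if nutrient == "AIA":
            continue
        mass_in = float(mass_in)
        if mass_in <= 0:
            out[nutrient] = float("nan")
            continue
        mass_out = float(fecal_conc.get(nutrient, np.nan)) * fecal_dm / 1000.0
        d = (mass_in - mass_out) / mass_in * 1000.0  # g/kg
        out[nutrient] = d
        if d < 0:
            out["flags"].append(nutrient)
    return out


def digestibility_table(intake: pd.DataFrame, feces: pd.DataFrame) -> pd.DataFrame:
    """Vectorised marker digestibility over cow-period tables.

    ``intake`` needs ``dmi_kg`` plus nutrient compositions ``*_g_per_kg``;
    ``feces`` the matching fecal concentrations.  DM digestibility follows
    from the marker-derived fecal DM output itself.
    """
    merged = intake.merge(feces, on=["cow_id", "period"], suffixes=("_in", "_fec"))
    rows = []
    for _, r in merged.iterrows():
        masses = {
            "DM": r["dmi_kg"],
            "OM": r["dmi_kg"] * r["OM_g_per_kg_in"] / 1000.0,
            "NDF": r["dmi_kg"] * r["NDF_g_per_kg_in"] / 1000.0,
            "CP": r["dmi_kg"] * r["CP_g_per_kg_in"] / 1000.0,
            "AIA": r["dmi_kg"] * r["AIA_g_per_kg_in"] / 1000.0,
        }
        conc = {
            "DM": 1000.0,  # feces is expressed per kg DM
            "OM": r["OM_g_per_kg_fec"],
            "NDF": r["NDF_g_per_kg_fec"],
            "CP": r["CP_g_per_kg_fec"],
            "AIA": r["AIA_g_per_kg_fec"],
        }
        res = marker_digestibility(masses, conc)
        rows.append(
            (r["cow_id"], r["period"], res["fecal_dm_kg"], res["DM"], res["OM"], res["NDF"], res["CP"])
        )
    return pd.DataFrame(
        rows, columns=["cow_id", "period", "fecal_dm_kg", "DM", "OM", "NDF", "CP"]
    )


def vfa_summaries(vfa: Mapping[str, float]) -> dict:
    """Summarise a VFA profile: major-acid proportions and (A+B)/P ratio.

    Input molar proportions are renormalized to sum to 100 mol/100 mol
    before reporting.  The ratio (acetate + butyrate)/propionate contrasts
    hydrogen-yielding against hydrogen-consuming fermentation.
    """
    vals = {k: float(v) for k, v in vfa.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("VFA proportions must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("VFA proportions must not all be zero")
    vals = {k: v * 100.0 / total for k, v in vals.items()}
    a = vals.get("acetate", 0.0)
    p = vals.get("propionate", 0.0)
    b = vals.get("butyrate", 0.0)
    if p == 0:
        raise ValueError("propionate proportion must be positive")
    return {
        "acetate": a,
        "propionate": p,
        "butyrate": b,
        "ratio_abp": (a + b) / p,
        "proportions": vals,
    }


def methane_intensity(rate: float, dmi: float, ecm: float) -> dict:
    """Methane intensity: g CH4 per kg dry-matter intake and per kg ECM."""
    if dmi <= 0 or ecm <= 0:
        raise ValueError("DMI and ECM must be positive")
    return {"per_kg_dmi": rate / dmi, "per_kg_ecm": rate / ecm}
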