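"""Scoring of the drug-repurposing viability screen.

Raw luminescence (RLU) wells are normalized against DMSO controls; each
drug's representative value is its treated relative viability at the
concentration where the treated/normoxic viability ratio is maximal; a drug
is called protective when that representative value lies more than one
standard deviation above the DMSO-treated control level and the drug does
not reduce viability in normoxia.  All calls are invariant to RLU units and
to the choice of DMSO reference condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screen_io import CONDITIONS, DMSO


def dmso_normalize(plates: pd.DataFrame, reference: str = "same") -> pd.DataFrame:
    """Add a ``relative_viability`` column: rlu / mean(DMSO rlu of a reference condition).

    ``reference='same'`` divides each well by the DMSO mean of its own
    condition (so DMSO averages 1 in both conditions); ``reference='normoxia'``
    divides every well by the normoxic DMSO mean, which keeps the treated
    control deficit (e.g. a 22% viability drop) visible in the normalized
    scale.  Protection calls are identical under either choice.
    """
    if reference not in ("same", "normoxia"):
        raise ValueError("reference must be 'same' or 'normoxia'")
    dmso = plates[plates["drug"] == DMSO]
    means = dmso.groupby("condition")["rlu"].mean()
    missing = [c for c in CONDITIONS if c not in means.index]
    if missing:
        raise ValueError(f"missing DMSO wells for condition(s) {missing}")
    out = plates.copy()
    if reference == "same":
        out["relative_viability"] = out["rlu"] / out["condition"].map(means)
    else:
        out["relative_viability"] = out["rlu"] / means["normoxia"]
    return out


def dmso_viability_drop(plates: pd.DataFrame) -> float:
    """Fractional viability loss of treated DMSO controls vs normoxic ones."""
    dmso = plates[plates["drug"] == DMSO]
    means = dmso.groupby("condition")["rlu"].mean()
    if not all(c in means.index for c in CONDITIONS):
        raise ValueError("need DMSO wells in both conditions")
    return float(1.0 - means["hypoxia_reoxygenation"] / means["normoxia"])


def representative_value(drug_table: pd.DataFrame) -> tuple[float, float]:
    """Representative (value, concentration) for one drug's normalized wells.

    For every concentration observed in both conditions, compute the ratio of
    treated to normoxic relative viability; pick the concentration maximizing
    that ratio (ties: lowest concentration) and return the treated relative
    viability there.
    """
    by_cc = drug_table.groupby(["concentration_nM", "condition"])["relative_viability"].mean().unstack()
    both = by_cc.dropna(subset=list(CONDITIONS)) if set(CONDITIONS) <= set(by_cc.columns) else by_cc.iloc[0:0]
    if both.empty:
        raise ValueError("no concentration observed in both conditions")
    ratio = both["hypoxia_reoxygenation"] / both["normoxia"]
    best = ratio.index[np.argmax(ratio.to_numpy())]  # index sorted ascending -> lowest conc wins ties
    return float(both.loc[best, "hypoxia_reoxygenation"]), float(best)


def call_protective(rep_value: float, dmso_treated_values, normoxic_at_rep: float,
                    dmso_normoxia_values, sd_multiplier: float = 1.0) -> bool:
    """Protection call for one drug.

    Protective iff the representative value exceeds the DMSO-treated mean by
    more than ``sd_multiplier`` sample standard deviations, and the normoxic
    relative viability at the representative concentration is not more than
    one normoxic-DMSO SD below 1 (a tolerance for 'not reducing viability in
    normoxia').  Requires at least two DMSO wells per condition so the SD is
    defined.
    """
    treated = np.asarray(dmso_treated_values, float)
    normox = np.asarray(dmso_normoxia_values, float)
    if len(treated) < 2 or len(normox) < 2:
        raise ValueError("need >= 2 DMSO wells per condition to define an SD")
    threshold = treated.mean() + sd_multiplier * treated.std(ddof=1)
    normoxia_ok = normoxic_at_rep >= normox.mean() - sd_multiplier * normox.std(ddof=1)
    return bool(rep_value > threshold and normoxia_ok)


def score_drugs(plates: pd.DataFrame, reference: str = "same",
                sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Full per-drug scoring of a plate table.

    Returns one row per non-DMSO drug: representative value and
    concentration, the normoxic relative viability at that concentration,
    and the protective / normoxia-toxic calls.
    """
    norm = dmso_normalize(plates, reference=reference)
    dmso = norm[norm["drug"] == DMSO]
    dmso_treated = dmso.loc[dmso["condition"] == "hypoxia_reoxygenation", "relative_viability"].to_numpy()
    dmso_normox = dmso.loc[dmso["condition"] == "normoxia", "relative_viability"].to_numpy()
    records = []
    for drug, sub in norm[norm["drug"] != DMSO].groupby("drug", sort=True):
        rep, conc = representative_value(sub)
        at_rep = sub[(sub["concentration_nM"] == conc) & (sub["condition"] == "normoxia")]
        normoxic_at_rep = float(at_rep["relative_viability"].mean())
        toxic = normoxic_at_rep < dmso_normox.mean() - sd_multiplier * np.std(dmso_normox, ddof=1)
        protective = call_protective(rep, dmso_treated, normoxic_at_rep, dmso_normox,
                                     sd_multiplier=sd_multiplier)
        records.append((drug, rep, conc, normoxic_at_rep, bool(protective), bool(toxic)))
    return pd.DataFrame(
        records,
        columns=["drug", "representative_value", "representative_concentration_nM",
                 "normoxic_at_representative", "protective", "normoxia_toxic"],
    )
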