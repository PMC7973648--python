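"""In silico hybrid construction and heterosis statistics.

Hybrid omics profiles are extrapolated from parental profiles by the
mid-parent rule: every hybrid feature value is the arithmetic mean of its
two parents' values. For homozygous (0/2-coded) parental genotypes this
yields hybrid dosages 0/1/2 with dosage 1 exactly where the parents
disagree; for transcript and metabolite layers it is the standard
additive extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CrossPlan, OmicsMatrix


@dataclass
class HybridProfileSet:
    """Per-layer hybrid omics matrices plus the cross plan that defined them."""

    profiles: dict[str, OmicsMatrix]
    plan: CrossPlan

    def __post_init__(self) -> None:
        for layer, om in self.profiles.items():
            if om.shape[0] != len(self.plan):
                raise ValueError(f"{layer}: row count differs from number of crosses")


def make_hybrid_profiles(parents: OmicsMatrix | dict[str, OmicsMatrix],
                         plan: CrossPlan) -> HybridProfileSet:
    """Cross parents in silico: hybrid row = mean of the two parental rows.

    Accepts a single parental layer or a dict of layers; every cross must
    reference parents present in each layer. Genomic parents are checked to
    be fully homozygous (dosages 0/2).
    """
    layers = parents if isinstance(parents, dict) else {parents.layer: parents}
    out: dict[str, OmicsMatrix] = {}
    for name, om in layers.items():
        index = set(om.data.index.astype(str))
        for _, row in plan.pairs.iterrows():
            for parent in (row["pollinator"], row["tester"]):
                if str(parent) not in index:
                    raise KeyError(
                        f"cross {row['hybrid']!r}: parent {parent!r} missing from "
                        f"{name} matrix"
                    )
        if om.layer == "genomic":
            vals = om.values
            if not np.all(np.isin(vals[np.isfinite(vals)], (0.0, 2.0))):
                raise ValueError("genomic parents must be homozygous (dosages 0/2)")
        p1 = om.data.loc[plan.pairs["pollinator"].astype(str)].to_numpy(dtype=float)
        p2 = om.data.loc[plan.pairs["tester"].astype(str)].to_numpy(dtype=float)
        hyb = pd.DataFrame((p1 + p2) / 2.0, index=plan.hybrids, columns=om.data.columns)
        out[name] = OmicsMatrix(hyb, om.layer)
    return HybridProfileSet(out, plan)


def mid_parent_heterosis(f1, p1, p2):
    """Mid-parent heterosis in percent: 100 * (F1 - MP) / MP, MP = (P1+P2)/2.

    Vectorized; a zero mid-parent value yields NaN with a warning.
    """
    f1, p1, p2 = (np.asarray(v, dtype=float) for v in (f1, p1, p2))
    mp = (p1 + p2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (f1 - mp) / mp
    bad = mp == 0
    if np.any(bad):
        warnings.warn("mid-parent value 0: MPH undefined, returned as NaN")
        out = np.where(bad, np.nan, out)
    return out if out.ndim else float(out)


def best_parent_heterosis(f1, p1, p2, larger_is_better: bool = True):
    """Best-parent heterosis in percent: 100 * (F1 - BP) / BP.

    BP is the better parent: the maximum for larger-is-better traits, the
    minimum otherwise (e.g. seed glucosinolate content). A zero best-parent
    value yields NaN with a warning.
    """
    f1, p1, p2 = (np.asarray(v, dtype=float) for v in (f1, p1, p2))
    bp = np.maximum(p1, p2) if larger_is_better else np.minimum(p1, p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (f1 - bp) / bp
    bad = bp == 0
    if np.any(bad):
        warnings.warn("best-parent value 0: BPH undefined, returned as NaN")
        out = np.where(bad, np.nan, out)
    return out if out.ndim else float(out)


def heterosis_table(hybrid_values: pd.Series, parent_values: pd.Series,
                    plan: CrossPlan, trait: str = "trait",
                    larger_is_better: bool = True) -> pd.DataFrame:
    """Long table of MPH and BPH per hybrid for one trait."""
    rows = []
    for _, row in plan.pairs.iterrows():
        h, p, t = row["hybrid"], str(row["pollinator"]), str(row["tester"])
        if h not in hybrid_values.index:
            continue
        f1, v1, v2 = hybrid_values[h], parent_values[p], parent_values[t]
        rows.append({
            "hybrid": h, "trait": trait,
            "MPH": mid_parent_heterosis(f1, v1, v2),
            "BPH": best_parent_heterosis(f1, v1, v2, larger_is_better),
        })
    return pd.DataFrame(rows, columns=["hybrid", "trait", "MPH", "BPH"])
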