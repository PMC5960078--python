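"""Set logic for BRM target classification.

A confident BRM target is a gene that is both BRM-bound (ChIP) and
differentially expressed upon wild-type BRM rescue in a depletion background.
Targets whose expression changes in the same direction under wild-type and
catalytically dead (K804R) BRM rescue are ATPase-independent; all other
targets — including the rare bound genes significant in both contrasts but
with opposite signs — are ATPase-dependent. A depletion-only contrast serves
as a control: few ATPase-independent genes should respond to mere BRM loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TargetClassification", "signed_calls", "classify_targets", "depletion_control"]


@dataclass
class TargetClassification:
    """Per-gene labels plus the marginal counts of the classification."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def independent_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["atpase_class"] == "independent"])

    def dependent_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["atpase_class"] == "dependent"])


def signed_calls(de: pd.DataFrame) -> pd.Series:
    """Collapse a DE result to per-gene signed calls: -1 down, +1 up, 0 not significant."""
    sig = de["significant"].to_numpy()
    sign = np.sign(de["log2fc"].to_numpy()).astype(int)
    return pd.Series(np.where(sig, sign, 0), index=de.index, dtype=int)


def classify_targets(
    bound: pd.Series,
    de_wt: pd.Series,
    de_mut: pd.Series,
    de_depl: pd.Series | None = None,
) -> TargetClassification:
    """Partition genes into ATPase-dependent / ATPase-independent targets.

    Inputs are per-gene series: ``bound`` boolean, the ``de_*`` series signed
    calls in {-1, 0, +1} for the wild-type-rescue, mutant-rescue and
    depletion-only contrasts. Gene universes are reconciled by intersection.

    Rules: target <=> bound and de_wt != 0; independent <=> target and
    de_mut != 0 and sign(de_wt) == sign(de_mut); dependent <=> target and not
    independent (discordant double-significant genes are dependent: they react
    differently to active and inactive BRM).
    """
    universe = bound.index.intersection(de_wt.index).intersection(de_mut.index)
    if de_depl is not None:
        universe = universe.intersection(de_depl.index)
    if len(universe) == 0:
        raise ValueError("empty intersection of binding and DE gene universes")
    universe = universe.sort_values()

    t = pd.DataFrame(index=universe)
    t["bound"] = bound.reindex(universe).astype(bool)
    t["de_wt"] = de_wt.reindex(universe).astype(int)
    t["de_mut"] = de_mut.reindex(universe).astype(int)
    t["de_depl"] = (
        de_depl.reindex(universe).astype(int) if de_depl is not None else 0
    )
    t["target"] = t["bound"] & (t["de_wt"] != 0)
    both = t["target"] & (t["de_mut"] != 0)
    t["concordant"] = both & (t["de_wt"] == t["de_mut"])
    t["atpase_class"] = np.where(
        t["concordant"], "independent", np.where(t["target"], "dependent", "none")
    )
    t["depl_overlap"] = (t["atpase_class"] == "independent") & (t["de_depl"] != 0)

    n_target = int(t["target"].sum())
    n_independent = int((t["atpase_class"] == "independent").sum())
    n_dependent = int((t["atpase_class"] == "dependent").sum())
    assert n_target == n_independent + n_dependent, "class partition broken"
    summary = {
        "n_genes": int(len(universe)),
        "n_bound": int(t["bound"].sum()),
        "n_de_wt": int((t["de_wt"] != 0).sum()),
        "n_target": n_target,
        "n_target_down": int((t["target"] & (t["de_wt"] < 0)).sum()),
        "n_target_up": int((t["target"] & (t["de_wt"] > 0)).sum()),
        "n_overlap_mut": int(both.sum()),
        "n_concordant": int(t["concordant"].sum()),
        "n_independent": n_independent,
        "n_dependent": n_dependent,
        "pct_independent": round(100.0 * n_independent / n_target, 2) if n_target else float("nan"),
        "n_depl_in_independent": int(t["depl_overlap"].sum()),
    }
    return TargetClassification(table=t, summary=summary)


def depletion_control(
    classification: TargetClassification, de_depl: pd.Series | None = None
) -> tuple[int, pd.Series]:
    """Count ATPase-independent genes that also respond to BRM depletion alone.

    If ``de_depl`` is given it overrides the calls stored at classification
    time. Returns the count and the per-gene boolean flags.
    """
    t = classification.table
    independent = t["atpase_class"] == "independent"
    if de_depl is not None:
        depl = de_depl.reindex(t.index).fillna(0).astype(int) != 0
    else:
        depl = t["de_depl"] != 0
    flags = independent & depl
    n = int(flags.sum())
    classification.summary["n_depl_in_independent"] = n
    return n, flags
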