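"""RT-qPCR relative quantification by the 2^-ddCT method.

Triplicate threshold cycles (CT) are averaged per sample and assay,
normalized against a reference small-RNA assay (dCT = CT_target -
CT_reference), referenced to the control-group mean dCT (ddCT), and
expressed as a per-sample fold change 2^-ddCT.  The group fold change
is the mean of per-sample fold changes in the case group, with its
standard error; group differences are tested with Welch's t on dCT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import welch_t


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles for one sample x assay, typically in triplicate."""

    sample: str
    condition: str
    assay: str
    cts: tuple

    def __post_init__(self):
        if len(self.cts) < 1:
            raise ValueError(f"{self.sample}/{self.assay}: no replicates")
        if any(c <= 0 for c in self.cts):
            raise ValueError(f"{self.sample}/{self.assay}: CT values must be positive")


#: replicate scatter above this SD (cycles) is flagged, not dropped
REPLICATE_SD_FLAG = 0.5


def summarize_ct(records: list[CtRecord]) -> pd.DataFrame:
    """Mean CT per sample x assay, with replicate SD and a scatter flag.

    Triples with replicate SD strictly greater than 0.5 cycles are
    flagged for inspection but retained; single-replicate entries are
    flagged (SD is undefined).
    """
    if not records:
        raise ValueError("no CT records")
    rows = []
    for rec in records:
        cts = np.asarray(rec.cts, dtype=float)
        sd = float(cts.std(ddof=1)) if len(cts) > 1 else float("nan")
        rows.append(
            {
                "sample": rec.sample,
                "condition": rec.condition,
                "assay": rec.assay,
                "mean_ct": float(cts.mean()),
                "replicate_sd": sd,
                "n_replicates": len(cts),
                "flagged": (len(cts) < 2) or (sd > REPLICATE_SD_FLAG),
            }
        )
    return pd.DataFrame(rows)


def ddct_fold_change(
    summary: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str,
) -> dict:
    """Per-sample dCT/ddCT/fold change and the case-group fold change.

    dCT_s = meanCT(target, s) - meanCT(reference, s); ddCT_s subtracts
    the control-group mean dCT.  The group fold change is the mean of
    per-sample 2^-ddCT among case samples (SE reported); the alternative
    2^-(mean case ddCT) is reported alongside.
    """
    tgt = summary[summary["assay"] == target].set_index("sample")
    ref = summary[summary["assay"] == reference].set_index("sample")
    if ref.empty:
        raise ValueError(f"reference assay {reference!r} not present")
    missing = set(tgt.index) ^ set(ref.index)
    if missing:
        raise ValueError(f"samples missing target or reference CT: {sorted(missing)}")
    per_sample = pd.DataFrame(
        {
            "condition": tgt["condition"],
            "dct": tgt["mean_ct"] - ref["mean_ct"],
        }
    )
    is_control = per_sample["condition"] == control_condition
    if not is_control.any():
        raise ValueError(f"no samples with control condition {control_condition!r}")
    per_sample["ddct"] = per_sample["dct"] - per_sample.loc[is_control, "dct"].mean()
    per_sample["fold_change"] = 2.0 ** (-per_sample["ddct"])
    case_fc = per_sample.loc[~is_control, "fold_change"]
    case_ddct = per_sample.loc[~is_control, "ddct"]
    return {
        "per_sample": per_sample,
        "group_fold_change": float(case_fc.mean()),
        "group_fold_change_se": float(case_fc.std(ddof=1) / np.sqrt(len(case_fc)))
        if len(case_fc) > 1
        else float("nan"),
        "group_fold_change_of_mean_ddct": float(2.0 ** (-case_ddct.mean())),
    }


def group_test(
    per_sample: pd.DataFrame,
    control_condition: str,
    column: str = "dct",
    tails: int = 2,
) -> tuple[float, float]:
    """Welch's t between case and control on per-sample dCT (or ddCT).

    ``tails=2`` for a validation design, ``tails=1`` for a directional
    replication design.
    """
    is_control = per_sample["condition"] == control_condition
    case = per_sample.loc[~is_control, column]
    control = per_sample.loc[is_control, column]
    return welch_t(case, control, tails=tails)


# ---------------------------------------------------------------------------
# IO


def read_ct_table(path) -> list[CtRecord]:
    """CT TSV with columns sample, condition, assay, rep1..repN."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    records = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        records.append(
            CtRecord(str(row["sample"]), str(row["condition"]), str(row["assay"]), cts)
        )
    return records


def write_ct_table(records: list[CtRecord], path) -> None:
    n_rep = max(len(r.cts) for r in records)
    rows = []
    for r in records:
        row = {"sample": r.sample, "condition": r.condition, "assay": r.assay}
        for i in range(n_rep):
            row[f"rep{i + 1}"] = r.cts[i] if i < len(r.cts) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
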