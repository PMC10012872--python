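"""qPCR relative quantification (2^-ddCt) and RNA-seq concordance.

Each sample's target Ct is normalized to the reference gene (rp49) in the
same sample (dCt), then to the mean dCt of the calibrator condition
(day 7) per gene (ddCt); relative quantity RQ = 2^-ddCt assumes perfect
amplification efficiency. Groups are compared by a two-sided Welch t-test
on ddCt (log-scale, approximately normal); a gene's qPCR call is
concordant "(+)" with RNA-seq when both are significant at 0.05 and the
direction of the day-42 RQ matches the sequencing direction call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "group_test", "concordance", "stars"]

logger = logging.getLogger(__name__)

REFERENCE_GENE = "rp49"


def stars(p: float) -> str:
    """Significance stars: '**' for p<0.01, '*' for 0.01<=p<0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    calibrator: str = "day7",
) -> pd.DataFrame:
    """Per-replicate dCt, ddCt and RQ from a tidy Ct table.

    ``ct`` has columns sample, condition, gene, ct. The reference gene must
    be measured in every sample and the calibrator condition present.
    Returns one row per (gene, sample) with columns gene, sample,
    condition, delta_ct, dd_ct, rq.
    """
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if calibrator not in set(ct["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} absent")

    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    missing = sorted(set(ct["sample"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in samples: {missing}"
        )

    out = ct[ct["gene"] != reference_gene].copy()
    out["delta_ct"] = out["ct"].values - ref.loc[out["sample"]].values
    cal_mean = (
        out[out["condition"] == calibrator]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    absent = sorted(set(out["gene"]) - set(cal_mean.index))
    if absent:
        raise ValueError(f"genes missing calibrator measurements: {absent}")
    out["dd_ct"] = out["delta_ct"].values - cal_mean.loc[out["gene"]].values
    out["rq"] = 2.0 ** (-out["dd_ct"])
    return out[["gene", "sample", "condition", "delta_ct", "dd_ct", "rq"]].reset_index(
        drop=True
    )


def group_test(
    rq: pd.DataFrame, calibrator: str = "day7", treatment: str = "day42"
) -> pd.DataFrame:
    """Welch t-test on ddCt between conditions, per gene.

    Returns one row per gene: replicate-mean and SD of RQ per condition,
    the mean log2 RQ of the treatment condition, p and stars. Requires
    >= 2 replicates per condition for every gene.
    """
    rows = []
    for gene, grp in rq.groupby("gene"):
        a = grp.loc[grp["condition"] == calibrator, "dd_ct"].values
        b = grp.loc[grp["condition"] == treatment, "dd_ct"].values
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"gene {gene!r}: need >=2 replicates per condition")
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(
            a.mean(), b.mean()
        ):
            p = 1.0  # identical groups: t = 0 by convention
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rq_b = grp.loc[grp["condition"] == treatment, "rq"]
        rq_a = grp.loc[grp["condition"] == calibrator, "rq"]
        rows.append(
            {
                "gene": gene,
                "rq_mean_calibrator": float(rq_a.mean()),
                "rq_sd_calibrator": float(rq_a.std(ddof=1)),
                "rq_mean_treatment": float(rq_b.mean()),
                "rq_sd_treatment": float(rq_b.std(ddof=1)),
                "log2_rq_treatment": float(np.log2(rq_b).mean()),
                "p": p,
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows).sort_values("gene", kind="stable").reset_index(drop=True)


def concordance(
    rq_summary: pd.DataFrame, de: pd.DataFrame, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Direction-concordance flags between qPCR and RNA-seq per gene.

    Concordant iff the sign of the mean log2 RQ at day 42 matches the DE
    direction call and both the qPCR t-test and the DE screen are
    significant (DE significance = direction != ns). Genes absent from the
    DE table get a null flag and are logged.
    """
    de_dir = dict(zip(de["feature"], de["direction"]))
    out = rq_summary.copy()
    flags: list[object] = []
    for _, r in out.iterrows():
        gene = r["gene"]
        if gene not in de_dir:
            logger.warning("gene %s missing from DE table; flag undefined", gene)
            flags.append(pd.NA)
            continue
        direction = de_dir[gene]
        qpcr_sig = r["p"] < p_cutoff
        qpcr_dir = "up" if r["log2_rq_treatment"] > 0 else "down"
        flags.append(bool(qpcr_sig and direction == qpcr_dir))
    out["concordant"] = flags
    return out
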