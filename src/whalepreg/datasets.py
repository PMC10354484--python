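"""Bundled dataset of PCFG female gray whale whale-years.

The fixture transcribes the published six-year study dataset: one row per
female whale-year with reproductive class (PF pregnant, LF lactating, JF
juvenile, MF mature of unknown status), sighting-history length and age
type, total-length posterior mean/sd (metres), aggregated log fP4m
(ng g^-1, natural log), aggregated W50 (unitless width/TL ratio), the
published per-model pregnancy probabilities with quartiles (reference
columns ``p_joint``/``p_fp4m``/``p_w50``), and next-year resighting info.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_pcfg_females", "model_matrix", "MODEL_VARIABLES"]

#: variables used by each classification model: the joint model uses both
#: log fP4m and W50; the univariate models one each.
MODEL_VARIABLES = {
    1: ["fp4m_log", "w50"],
    2: ["fp4m_log"],
    3: ["w50"],
}

#: published point-probability column for each model.
MODEL_PROB_COLUMN = {1: "p_joint", 2: "p_fp4m", 3: "p_w50"}


def load_pcfg_females() -> pd.DataFrame:
    """Load the bundled whale-year dataset as a DataFrame."""
    with resources.files("whalepreg.data").joinpath("pcfg_females.csv").open() as fh:
        df = pd.read_csv(fh)
    df["record_id"] = df["whale_id"] + ":" + df["year"].astype(str)
    return df


def model_matrix(df: pd.DataFrame, model: int):
    """Records usable by a model: (X, forced_mask, record_ids).

    Rows with any required variable missing are dropped; the forced mask
    marks confirmed-pregnant (PF) whale-years, which the bootstrap keeps
    in every sample.
    """
    try:
        cols = MODEL_VARIABLES[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected 1, 2 or 3") from None
    sub = df.dropna(subset=cols)
    X = sub[cols].to_numpy(dtype=float)
    if X.shape[1] == 1:
        X = X[:, 0]
    forced = (sub["group"] == "PF").to_numpy()
    return X, forced, sub["record_id"].to_numpy(), sub
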