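"""Feature normalization (train-cohort z-scores) and post-minus-pre deltas.

Normalization statistics are fit on the pooled pre+post values of the
training cohort only and reused verbatim on validation data (no leakage);
zero-variance features are dropped with a warning.  By default features
are normalized first and differenced second; the reverse order is
available as a sensitivity switch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NormalizationStats:
    mean: pd.Series
    sd: pd.Series
    dropped: list
    provenance: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mean": self.mean.to_dict(),
                "sd": self.sd.to_dict(),
                "dropped": list(self.dropped),
                "provenance": self.provenance,
            }, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NormalizationStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(pd.Series(d["mean"]), pd.Series(d["sd"]),
                   d["dropped"], d.get("provenance", ""))


def fit_normalization(train_table: pd.DataFrame,
                      provenance: str = "") -> NormalizationStats:
    """Per-feature mean and SD (n-1) over the training rows.

    Applying the stats back to the training table gives column mean 0 and
    SD 1.  Constant columns are dropped and logged.
    """
    num = train_table.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need >= 2 rows to fit normalization")
    mean = num.mean()
    sd = num.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("dropping %d zero-variance features (e.g. %s)",
                       len(dropped), dropped[:3])
    # means are kept for every column (dropped ones can still be centred);
    # scaling stats exist only for retained features
    keep = [c for c in num.columns if c not in dropped]
    return NormalizationStats(mean, sd[keep], dropped, provenance)


def apply_normalization(stats: NormalizationStats, table: pd.DataFrame,
                        keep_dropped: bool = False) -> pd.DataFrame:
    """z-score ``table`` with training statistics.

    Fitted columns missing from the table raise.  With ``keep_dropped``,
    columns the fit dropped for zero training variance are retained,
    centred on their training value but unscaled, so the feature pool keeps
    its full width (their training deltas are identically 0 and carry no
    signal into selection).
    """
    fitted = list(stats.sd.index)
    missing = [c for c in fitted if c not in table.columns]
    if missing:
        raise ValueError(f"table missing fitted features: {missing[:5]}")
    pieces = {c: (table[c] - stats.mean[c]) / stats.sd[c] for c in fitted}
    if keep_dropped:
        for c in stats.dropped:
            if c in table.columns:
                pieces[c] = table[c] - stats.mean[c]
    out = pd.DataFrame(pieces, index=table.index)
    out = out[[c for c in table.columns if c in out.columns]]
    for c in table.columns:
        if c not in out.columns and not pd.api.types.is_numeric_dtype(table[c]):
            out[c] = table[c]
    return out


def compute_delta(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """post - pre, per feature, rows aligned on index (patient id).

    Raises on patient mismatch; antisymmetric by construction.
    """
    if not pre.index.equals(post.index):
        if set(pre.index) != set(post.index):
            raise ValueError("patient mismatch between pre and post tables")
        post = post.loc[pre.index]
    cols = [c for c in pre.columns if c in post.columns
            and pd.api.types.is_numeric_dtype(pre[c])]
    if list(pre[cols].columns) != list(post[cols].columns):
        raise ValueError("feature mismatch between pre and post tables")
    return post[cols] - pre[cols]
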