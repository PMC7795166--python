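"""Per-individual under-sampling to equalise behaviour classes.

Behaviour classes in free-living recordings are wildly imbalanced (quiet
lying dominates; locomotor play is rare).  Before training, each
(animal file, behaviour) group is capped at ``floor(s_min / k_b)`` windows,
where ``s_min`` is the total budget per behaviour — by default the total
window count of the rarest behaviour — and ``k_b`` is the number of files
containing at least one window of behaviour ``b``.  Groups below the cap
are kept whole; groups above it are thinned by uniform sampling without
replacement.  Capping per file (rather than globally) balances each
individual's contribution as well as each class's total.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ethogram


@dataclass
class BalanceSpec:
    """Parameters of the under-sampling scheme.

    s_min : total target sample count per behaviour, or None to use the
        total count of the rarest behaviour present in the data.
    seed : master seed; each (file, behaviour) group draws from its own
        derived stream so the result is independent of iteration order.
    """

    s_min: int | None = None
    seed: int = 0


def per_file_cap(s_min: int, k_b: int) -> int:
    """Per-file retention cap floor(s_min / k_b) for one behaviour.

    Flooring keeps the per-behaviour total within the s_min budget when
    s_min is not divisible by the number of contributing files.
    """
    if k_b < 1:
        raise ValueError("behaviour absent from every file (k_b = 0)")
    if s_min < 1:
        raise ValueError("s_min must be positive")
    cap = s_min // k_b
    if cap < 1:
        raise ValueError(
            f"cap floor({s_min}/{k_b}) = 0: s_min too small for {k_b} files "
            "(cap must be >= 1)"
        )
    return cap


def _group_rng(seed: int, animal_id: str, behaviour: str) -> np.random.Generator:
    # Stable per-group stream: master seed + crc32 of the file id + the
    # behaviour's ethogram index.  Independent of group iteration order.
    file_key = zlib.crc32(str(animal_id).encode())
    try:
        beh_key = ethogram.behaviour_index(behaviour)
    except KeyError:
        beh_key = zlib.crc32(str(behaviour).encode())
    return np.random.default_rng([seed, file_key, beh_key])


def balance(
    frame: pd.DataFrame,
    spec: BalanceSpec,
    label_col: str = "behaviour",
    file_col: str = "animal_id",
) -> pd.DataFrame:
    """Apply the per-file cap to a labelled window table.

    Returns a sub-multiset of the input rows (original index preserved,
    output sorted by it).  Unlabelled rows must be dropped beforehand.
    """
    if frame.empty:
        raise ValueError("cannot balance an empty dataset")
    if frame[label_col].isna().any():
        raise ValueError("dataset contains unlabelled rows; drop them before balancing")
    s_min = spec.s_min
    if s_min is None:
        s_min = int(frame[label_col].value_counts().min())
    keep_index: list[np.ndarray] = []
    k_by_behaviour = frame.groupby(label_col, observed=True)[file_col].nunique()
    for (animal_id, behaviour), group in frame.groupby([file_col, label_col], observed=True):
        cap = per_file_cap(s_min, int(k_by_behaviour[behaviour]))
        if len(group) > cap:
            rng = _group_rng(spec.seed, animal_id, behaviour)
            chosen = rng.choice(group.index.to_numpy(), size=cap, replace=False)
            keep_index.append(np.sort(chosen))
        else:
            keep_index.append(group.index.to_numpy())
    kept = np.sort(np.concatenate(keep_index))
    return frame.loc[kept]


def retention_report(
    original: pd.DataFrame,
    balanced: pd.DataFrame,
    label_col: str = "behaviour",
    file_col: str = "animal_id",
) -> pd.DataFrame:
    """Per-(file, behaviour) before/after counts for audit."""
    before = original.groupby([file_col, label_col], observed=True).size().rename("n_before")
    after = balanced.groupby([file_col, label_col], observed=True).size().rename("n_after")
    report = pd.concat([before, after], axis=1).fillna(0).astype(int).reset_index()
    report["n_dropped"] = report["n_before"] - report["n_after"]
    return report
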