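"""Binarization of continuous multichannel signals into ±1 activity patterns."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class BinaryTimeSeries:
    """A ``(T, N)`` matrix over {+1, −1} with node labels.

    ``values[t, i]`` is the binary activity of node ``i`` at time ``t``.
    """

    values: np.ndarray
    node_names: list[str] = field(default_factory=list)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a (T, N) matrix")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one timepoint")
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("entries must be +1 or -1")
        if not self.node_names:
            self.node_names = [f"node{i}" for i in range(self.values.shape[1])]
        if len(self.node_names) != self.values.shape[1]:
            raise ValueError("node_names length must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        """Write the ±1 matrix as TSV with node names as header."""
        import pandas as pd

        pd.DataFrame(self.values, columns=self.node_names).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, subject_id: str | None = None) -> "BinaryTimeSeries":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        return cls(
            values=frame.to_numpy(dtype=np.int8),
            node_names=list(frame.columns),
            subject_id=subject_id,
        )


def binarize(
    signals: np.ndarray,
    mode: str = "per-timepoint-mean",
    node_names: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> BinaryTimeSeries:
    """Threshold continuous node signals into ±1 activity patterns.

    Parameters
    ----------
    signals
        ``(T, N)`` real matrix of node signals (e.g. network-averaged
        rsfMRI time series).
    mode
        ``"per-timepoint-mean"`` (default) thresholds each timepoint at the
        mean of the N node signals at that timepoint (the "global signal"
        threshold, which balances the counts of active and inactive
        entries); ``"per-node-temporal-mean"`` thresholds each node at its
        own temporal mean.

    An entry is +1 when the signal strictly exceeds its threshold and −1
    otherwise; ties (signal equal to threshold) map to −1, which makes the
    rule deterministic and is measure-zero for real-valued data.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be a (T, N) matrix")
    if signals.shape[1] < 2:
        raise ValueError("need at least two nodes")
    if not np.isfinite(signals).all():
        raise ValueError("signals contain NaN or Inf entries")
    if mode == "per-timepoint-mean":
        threshold = signals.mean(axis=1, keepdims=True)
    elif mode == "per-node-temporal-mean":
        threshold = signals.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown binarization mode {mode!r}")
    values = np.where(signals > threshold, 1, -1).astype(np.int8)
    return BinaryTimeSeries(
        values=values,
        node_names=list(node_names) if node_names is not None else [],
        subject_id=subject_id,
    )
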