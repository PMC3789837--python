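"""Serial-section electron-microscopy microtubule length estimation.

In serial reconstructions of neurite segments, individual microtubules are
much longer than the reconstructed window, so their lengths cannot be read
off directly. With N microtubule profiles per section on average over a
reconstructed length of a (µm), the total microtubule length inside the
window is N·a; each microtubule contributes two endpoints, so T observed
endpoints correspond to T/2 microtubules and the mean length is

    L = 2·N·a / T    (µm).

The estimator assumes endpoints fall uniformly in the window and that
microtubules are long relative to section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import pandas as pd

__all__ = ["MtReconstruction", "mt_mean_length", "append_length_column"]


@dataclass(frozen=True)
class MtReconstruction:
    """One serial-section reconstruction.

    N: mean number of microtubules per section (dimensionless);
    a: total reconstructed length (µm);
    T: number of microtubule endpoints observed.
    """

    N: float
    a: float
    T: int

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError(f"mean microtubule count N must be >= 0, got {self.N}")
        if self.a <= 0:
            raise ValueError(f"reconstructed length a must be > 0, got {self.a}")
        if self.T < 0:
            raise ValueError(f"endpoint count T must be >= 0, got {self.T}")


def mt_mean_length(rec: MtReconstruction) -> float:
    """Mean microtubule length L = 2·N·a/T in µm; requires T > 0."""
    if rec.T == 0:
        raise ValueError("no microtubule endpoints observed; mean length is undefined")
    return 2.0 * rec.N * rec.a / rec.T


def append_length_column(in_stream: TextIO, out_stream: TextIO) -> pd.DataFrame:
    """Read a 3-column TSV (N, a, T), append an L column, write TSV.

    Returns the augmented table.
    """
    df = pd.read_csv(in_stream, sep="\t", comment="#")
    required = {"N", "a", "T"}
    if not required <= set(df.columns):
        raise ValueError(f"input must have columns {sorted(required)}, got {list(df.columns)}")
    df["L"] = [
        mt_mean_length(MtReconstruction(N=float(r.N), a=float(r.a), T=int(r.T)))
        for r in df.itertuples()
    ]
    df.to_csv(out_stream, sep="\t", index=False)
    return df
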