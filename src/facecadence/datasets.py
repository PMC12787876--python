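"""Packaged benchmark fixture: per-trial cadence triples.

The bundled table holds, for 11 participants at three treadmill speeds
(6, 8, 10 km/h), the mean cadence estimated by the FFT-Corrected method,
the peak-detection baseline, and the video-based ground truth, in
steps/min. It is the reference dataset for the agreement battery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import PairedSeries

__all__ = ["load_table2", "table2_series"]

_EXPECTED_SHAPE = (33, 5)


def load_table2() -> pd.DataFrame:
    """The per-trial cadence comparison table as a DataFrame.

    Columns: participant (1-11), speed_kmh (6/8/10), fft_spm, peaks_spm,
    video_spm. Exactly 11 participants x 3 speeds = 33 rows.
    """
    with resources.files("facecadence.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    if df.shape != _EXPECTED_SHAPE:
        raise RuntimeError(f"fixture corrupted: shape {df.shape}")
    counts = df.groupby("speed_kmh")["participant"].nunique()
    if not (counts == 11).all() or len(counts) != 3:
        raise RuntimeError("fixture corrupted: expected 11 participants x 3 speeds")
    return df


def table2_series(method: str = "fft") -> PairedSeries:
    """Paired (estimate, truth) series for one method from the fixture.

    ``method`` is ``"fft"`` (FFT-Corrected) or ``"peaks"`` (the
    peak-detection baseline, called "Derivative" in some summaries).
    """
    df = load_table2()
    col = {"fft": "fft_spm", "peaks": "peaks_spm"}.get(method)
    if col is None:
        raise ValueError(f"unknown method {method!r}; use 'fft' or 'peaks'")
    labels = tuple(
        (int(p), int(s)) for p, s in zip(df["participant"], df["speed_kmh"])
    )
    return PairedSeries(
        estimate=df[col].to_numpy(),
        truth=df["video_spm"].to_numpy(),
        labels=labels,
    )
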