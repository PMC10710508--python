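"""Glycan microarray signal processing.

Polysaccharide extracts (sequential H2O, EDTA, NaOH extractions) are
printed in quadruplicate and probed with glycan-specific monoclonal
antibodies. Processing chain: the highest spot signal in the data set
(a standard control) is set to 100 and all signals scaled accordingly;
antibodies with a normalized signal >= 5 in at least one sample are
retained; replicate spots are averaged; and per (sample, antibody) the
three extraction means are summed into the epitope abundance table.

Antibody avidities differ, so values are comparable only within one
antibody across samples — no cross-antibody statistic is emitted.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "EXTRACTIONS",
    "normalize_to_max",
    "replicate_means",
    "filter_antibodies",
    "sum_extractions",
    "process_microarray",
]

EXTRACTIONS = ("H2O", "EDTA", "NaOH")

_KEY = ["sample", "extraction", "antibody"]


def normalize_to_max(signals: pd.DataFrame) -> pd.DataFrame:
    """Scale all signals so the data-set maximum is exactly 100.

    Standard-control spots participate in finding the maximum (the assay
    design places the strongest signal on a control spot).
    """
    peak = signals["signal"].max()
    if not peak > 0:
        raise ValueError("all signals are zero; normalization undefined")
    out = signals.copy()
    out["signal"] = out["signal"] * (100.0 / peak)
    return out


def replicate_means(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized signal per (sample, extraction, antibody).

    Standard-control spots are excluded: they exist only to anchor the
    normalization. The replicate count behind each mean is reported.
    """
    epitopes = normalized[normalized["is_control"] == 0]
    out = (
        epitopes.groupby(_KEY, as_index=False)
        .agg(mean_signal=("signal", "mean"), n_replicates=("signal", "size"))
    )
    return out


def filter_antibodies(
    means: pd.DataFrame, threshold: float = 5.0
) -> pd.DataFrame:
    """Retain antibodies with mean signal >= threshold in >= one sample.

    The comparison is non-strict (>= 5 as stated); the maximum is taken
    over every (sample, extraction) mean of the antibody.
    """
    best = means.groupby("antibody")["mean_signal"].max()
    keep = set(best[best >= threshold].index)
    return means[means["antibody"].isin(keep)].reset_index(drop=True)


def sum_extractions(filtered_means: pd.DataFrame) -> pd.DataFrame:
    """Sum the H2O, EDTA and NaOH extraction means per (sample, antibody).

    A missing extraction contributes 0; an unknown extraction label is an
    error.
    """
    bad = set(filtered_means["extraction"]) - set(EXTRACTIONS)
    if bad:
        raise ValueError(f"unknown extraction labels: {sorted(bad)}")
    out = (
        filtered_means.groupby(["sample", "antibody"], as_index=False)
        .agg(summed_mean_signal=("mean_signal", "sum"))
    )
    return out


def process_microarray(
    signals: pd.DataFrame,
    threshold: float = 5.0,
    filter_on: str = "mean",
) -> pd.DataFrame:
    """Full chain: normalize -> replicate means -> >=5 filter -> extraction sums.

    ``filter_on='mean'`` judges retention on replicate means (default);
    ``'spot'`` judges it on individual normalized spot signals before
    averaging (the stricter-to-drop reading of the prose order).
    Returns the epitope abundance table (sample, antibody,
    summed_mean_signal) on the 0–100 normalized scale.
    """
    if filter_on not in ("mean", "spot"):
        raise ValueError("filter_on must be 'mean' or 'spot'")
    norm = normalize_to_max(signals)
    means = replicate_means(norm)
    if filter_on == "mean":
        kept = filter_antibodies(means, threshold)
    else:
        spots = norm[norm["is_control"] == 0]
        best = spots.groupby("antibody")["signal"].max()
        keep = set(best[best >= threshold].index)
        kept = means[means["antibody"].isin(keep)].reset_index(drop=True)
    return sum_extractions(kept)
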