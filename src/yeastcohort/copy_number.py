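"""Per-ORF and per-bin absolute copy number from depth tables.

Depth is compared to the sample's base coverage -- the median of
length-normalized ORF depths -- on the log2 scale; absolute copy number is
the ploidy-scaled ratio, so a gene at exactly the median depth in a diploid
has CN = 2 and a 200x segment against a median of 100 has a log2 ratio of 1.
Binned log2 tracks are smoothed with a three-state (loss/neutral/gain)
Gaussian HMM and merged into segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

ZERO_DEPTH_FLOOR = 0.5  # reads; keeps log2 ratios finite at zero depth


def log2_ratio(segment_depth, base_coverage: float, floor: float = ZERO_DEPTH_FLOOR):
    """log2 of segment depth over base (median) coverage.

    Zero segment depth is clamped to ``floor`` so the ratio stays finite;
    downstream rounding then sends such segments to CN 0.
    """
    if base_coverage <= 0:
        raise ValueError("base coverage must be > 0")
    seg = np.maximum(np.asarray(segment_depth, dtype=float), floor)
    out = np.log2(seg / base_coverage)
    return float(out) if np.isscalar(segment_depth) else out


def orf_copy_number(orf_depths: pd.Series, ploidy: int) -> pd.Series:
    """Absolute per-ORF CN for one strain.

    CN(gene) = ploidy x 2^(log2 ratio of the gene's length-normalized depth
    against the sample median of length-normalized ORF depths).  The median
    estimated CN therefore equals the ploidy by construction, and the result
    is invariant to rescaling all depths by a constant.
    """
    if ploidy not in (2, 3):
        raise ValueError("ploidy must be 2 or 3")
    depths = orf_depths.astype(float)
    if len(depths) < 1:
        raise ValueError("need at least one ORF")
    base = float(depths.median())
    if base <= 0:
        raise ValueError("all-zero depth table")
    return pd.Series(
        ploidy * np.power(2.0, log2_ratio(depths.to_numpy(), base)),
        index=depths.index,
    )


def cn_profiles(orf_depth: pd.DataFrame, ploidy: dict[str, int]) -> pd.DataFrame:
    """Strains x genes continuous CN from a strains x genes depth table."""
    rows = {
        strain: orf_copy_number(orf_depth.loc[strain], ploidy[strain])
        for strain in orf_depth.index
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=orf_depth.columns)


def segment_track(
    bins: pd.DataFrame,
    n_states: int = 3,
    stay_prob: float = 0.99,
    state_means: tuple[float, ...] = (-1.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Merge a binned log2 track into loss/neutral/gain segments.

    ``bins`` needs columns chrom, start, end, log2 (ordered within each
    chromosome).  Emission sigma is estimated from the track's median
    absolute deviation; the transition matrix has ``stay_prob`` on the
    diagonal.  Viterbi decoding is followed by merging adjacent same-state
    bins; per-segment ratio is the mean of member bins.
    """
    if len(bins) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_bins", "state", "log2"])
    values = bins["log2"].to_numpy(dtype=float)
    mad = float(np.median(np.abs(values - np.median(values))))
    sigma = max(1.4826 * mad, 0.05)
    k = n_states
    model = GaussianHMM(n_components=k, covariance_type="spherical", init_params="")
    model.startprob_ = np.full(k, 1.0 / k)
    off = (1.0 - stay_prob) / (k - 1)
    model.transmat_ = np.full((k, k), off) + np.eye(k) * (stay_prob - off)
    model.means_ = np.asarray(state_means, dtype=float).reshape(-1, 1)
    model.covars_ = np.full(k, sigma**2)
    state_labels = {i: name for i, name in zip(range(k), ("loss", "neutral", "gain"))}

    segments = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        x = sub["log2"].to_numpy(dtype=float).reshape(-1, 1)
        if len(x) == 1:
            states = np.array([int(np.argmin(np.abs(np.asarray(state_means) - x[0, 0])))])
        else:
            states = model.predict(x)
        start_i = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[start_i]:
                chunk = sub.iloc[start_i:i]
                segments.append(
                    {
                        "chrom": chrom,
                        "start": int(chunk["start"].iloc[0]),
                        "end": int(chunk["end"].iloc[-1]),
                        "n_bins": len(chunk),
                        "state": state_labels.get(int(states[start_i]), str(states[start_i])),
                        "log2": float(chunk["log2"].mean()),
                    }
                )
                start_i = i
    return pd.DataFrame(segments)
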