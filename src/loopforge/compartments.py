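"""A/B compartment calling, replicate majority labels and shift statistics.

Compartments are assigned from the sign of the first eigenvector of the
correlation matrix of the observed-over-expected map, oriented so the
eigenvector correlates positively with an activity track (A = active).
Per-replicate labels are combined with a strict >70% majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic import ContactMatrix, oe_transform

__all__ = ["CompartmentTrack", "compartment_eigenvector", "majority_label", "shift_stats", "sample_pca"]

AMBIGUOUS = "ambiguous"


@dataclass
class CompartmentTrack:
    bin_size: int
    pc1: np.ndarray
    labels: np.ndarray  # 'A' / 'B' / 'ambiguous' per bin
    degenerate: bool = False

    def __post_init__(self) -> None:
        allowed = {"A", "B", AMBIGUOUS}
        if not set(np.unique(self.labels)) <= allowed:
            raise ValueError("labels outside {A, B, ambiguous}")


def compartment_eigenvector(matrix: ContactMatrix, activity_track: np.ndarray) -> CompartmentTrack:
    """First eigenvector of the O/E correlation matrix, sign-oriented.

    The sign of the eigenvector is arbitrary; it is fixed so that its
    correlation with ``activity_track`` (any per-bin activity proxy, e.g.
    gene density or an active histone mark) is positive, and bins with
    positive values are labeled A.
    """
    activity_track = np.asarray(activity_track, dtype=float)
    if activity_track.shape[0] != matrix.n_bins:
        raise ValueError("activity track length must equal n_bins")
    oe = oe_transform(matrix)
    sd = oe.std(axis=0)
    covered = sd > 0
    n = matrix.n_bins
    pc1 = np.zeros(n)
    labels = np.full(n, AMBIGUOUS, dtype=object)
    if covered.sum() < 2:
        return CompartmentTrack(matrix.resolution, pc1, labels, degenerate=True)

    sub = oe[np.ix_(covered, covered)]
    corr = np.corrcoef(sub)
    if not np.isfinite(corr).all() or np.allclose(corr, corr.flat[0]):
        return CompartmentTrack(matrix.resolution, pc1, labels, degenerate=True)

    vals, vecs = np.linalg.eigh(corr)
    vec = vecs[:, -1]  # leading eigenvalue
    if np.allclose(vec, vec[0]):
        return CompartmentTrack(matrix.resolution, pc1, labels, degenerate=True)

    act = activity_track[covered]
    if np.std(act) > 0 and np.std(vec) > 0:
        if np.corrcoef(vec, act)[0, 1] < 0:
            vec = -vec
    pc1[covered] = vec
    lab = np.where(vec > 0, "A", np.where(vec < 0, "B", AMBIGUOUS))
    labels[covered] = lab
    return CompartmentTrack(matrix.resolution, pc1, labels.astype(object))


def majority_label(replicate_tracks: list[CompartmentTrack], threshold: float = 0.70) -> CompartmentTrack:
    """Strict majority vote: A iff > threshold of replicates call A."""
    if not replicate_tracks:
        raise ValueError("need at least one replicate track")
    n = replicate_tracks[0].labels.shape[0]
    if any(t.labels.shape[0] != n for t in replicate_tracks):
        raise ValueError("replicate tracks on mismatched bin grids")
    stack = np.stack([t.labels for t in replicate_tracks])
    n_rep = len(replicate_tracks)
    frac_a = (stack == "A").sum(axis=0) / n_rep
    frac_b = (stack == "B").sum(axis=0) / n_rep
    labels = np.full(n, AMBIGUOUS, dtype=object)
    labels[frac_a > threshold] = "A"
    labels[frac_b > threshold] = "B"
    pc1 = np.mean(np.stack([t.pc1 for t in replicate_tracks]), axis=0)
    return CompartmentTrack(replicate_tracks[0].bin_size, pc1, labels)


def shift_stats(track_a: CompartmentTrack, track_b: CompartmentTrack, denominator: str = "informative"):
    """Compartment-shift percentages between two conditions.

    ``B_to_A`` means B in ``track_a`` and A in ``track_b``.  Percentages
    are over bins unambiguous in both tracks (``denominator="informative"``,
    the default) or over all bins (``denominator="all"``).
    """
    la, lb = track_a.labels, track_b.labels
    if la.shape != lb.shape:
        raise ValueError("tracks on mismatched bin grids")
    informative = (la != AMBIGUOUS) & (lb != AMBIGUOUS)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError("no bins unambiguous in both tracks")
    denom = la.shape[0] if denominator == "all" else n_inf
    b_to_a = int(((la == "B") & (lb == "A")).sum())
    a_to_b = int(((la == "A") & (lb == "B")).sum())
    stable = int((informative & (la == lb)).sum())
    return {
        "percent_B_to_A": 100.0 * b_to_a / denom,
        "percent_A_to_B": 100.0 * a_to_b / denom,
        "percent_stable": 100.0 * stable / denom,
        "n_informative": n_inf,
    }


def sample_pca(feature_matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Centered PCA scores of a samples x features value matrix."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 samples")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, s.size)
    return u[:, :k] * s[:k]
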