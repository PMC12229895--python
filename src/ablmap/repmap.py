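"""Representational similarity matrices, summaries, embeddings, decoding.

The representational map of one FOV on one day is the 34x34 matrix of
Pearson correlations between stimulus population vectors.  In
``single_trial`` mode each element averages the correlations of all
trial-vector pairs for the stimulus pair, excluding identical-trial pairings
on the diagonal (so with T=10 trials a diagonal element averages C(10,2)=45
pair correlations and an off-diagonal element 100); the diagonal then
measures trial-to-trial reliability of the population response.  In
``trial_averaged`` mode vectors are first averaged across trials and the
diagonal is identically 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._rng import child_seed
from .dataset import TrialTensor


@dataclass
class SimilarityMatrix:
    """Stimulus-pair correlation matrix with mode tag and provenance."""

    M: np.ndarray
    mode: str  # "single_trial" | "trial_averaged"
    fov_id: str
    day: int
    n_neurons: int


def similarity_matrix(
    tensor: TrialTensor,
    mode: str = "single_trial",
    neuron_mask: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Build the similarity matrix from one FOV-day tensor.

    ``neuron_mask`` restricts the population (e.g. spared neurons); absent
    neurons are always dropped.  Zero-variance population vectors are
    excluded from the elements they would enter.
    """
    if mode not in ("single_trial", "trial_averaged"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = tensor.present.copy()
    if neuron_mask is not None:
        mask &= np.asarray(neuron_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError(f"need at least 2 neurons, got {int(mask.sum())}")
    A = tensor.A[mask]  # (N, S, T)
    N, S, T = A.shape
    if mode == "trial_averaged":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            V = np.nanmean(A, axis=2)  # (N, S)
        M = _corr_columns(V)
        np.fill_diagonal(M, 1.0)
    else:
        if T < 2:
            raise ValueError("single_trial mode needs at least 2 trials per stimulus")
        # stack all S*T single-trial vectors and correlate once
        X = A.reshape(N, S * T).T  # (S*T, N)
        Z, ok = _standardize_rows(X)
        R = np.full((S * T, S * T), np.nan)
        R[np.ix_(ok, ok)] = (Z[ok] @ Z[ok].T) / N
        M = np.empty((S, S))
        for s1 in range(S):
            for s2 in range(s1, S):
                block = R[s1 * T : (s1 + 1) * T, s2 * T : (s2 + 1) * T]
                if s1 == s2:
                    vals = block[np.triu_indices(T, k=1)]  # exclude same-trial pairings
                else:
                    vals = block.reshape(-1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    M[s1, s2] = M[s2, s1] = np.nanmean(vals)
    return SimilarityMatrix(M=M, mode=mode, fov_id=tensor.fov_id, day=tensor.day, n_neurons=int(N))


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = (sd[:, 0] > 0) & np.isfinite(X).all(axis=1)
    Z = np.zeros_like(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z, ok


def _corr_columns(V: np.ndarray) -> np.ndarray:
    """Correlation matrix of the columns of (N, S) across the N axis."""
    Z, ok = _standardize_rows(V.T)
    S = V.shape[1]
    M = np.full((S, S), np.nan)
    M[np.ix_(ok, ok)] = (Z[ok] @ Z[ok].T) / V.shape[0]
    return M


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class MapSummary:
    """Per-day diagonal/off-diagonal means of grand-average matrices."""

    frame: pd.DataFrame  # day, n_fovs, diag_mean, offdiag_mean, diag_norm, offdiag_norm
    grand: dict          # {day: grand-average matrix}


def summarize_map(matrices: list[SimilarityMatrix], baseline_days: tuple[int, ...] = (1, 3, 5)) -> MapSummary:
    """Grand-average matrices per day with diagonal / off-diagonal summaries.

    Matrices are averaged elementwise across FOVs for each day; the diagonal
    mean averages the 34 diagonal entries and the off-diagonal mean the
    unordered stimulus pairs (each counted once).  Normalised variants divide
    by the mean of the metric over ``baseline_days``.
    """
    if not matrices:
        raise ValueError("no similarity matrices given")
    modes = {m.mode for m in matrices}
    shapes = {m.M.shape for m in matrices}
    if len(modes) > 1 or len(shapes) > 1:
        raise ValueError("matrices must share mode and stimulus set")
    by_day: dict[int, list[SimilarityMatrix]] = {}
    for m in matrices:
        by_day.setdefault(m.day, []).append(m)
    grand, rows = {}, []
    for day in sorted(by_day):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            G = np.nanmean(np.stack([m.M for m in by_day[day]]), axis=0)
        grand[day] = G
        S = G.shape[0]
        iu = np.triu_indices(S, k=1)
        rows.append((day, len(by_day[day]), float(np.nanmean(np.diag(G))), float(np.nanmean(G[iu]))))
    frame = pd.DataFrame(rows, columns=["day", "n_fovs", "diag_mean", "offdiag_mean"])
    base = frame[frame["day"].isin(baseline_days)]
    for col in ("diag_mean", "offdiag_mean"):
        b = base[col].mean()
        if not b > 0:
            raise ValueError(f"normalisation baseline for {col} must be positive, got {b}")
        frame[col.replace("_mean", "_norm")] = frame[col] / b
    return MapSummary(frame=frame, grand=grand)


# ---------------------------------------------------------------------------
# classical MDS embedding
# ---------------------------------------------------------------------------

def mds_embed(sim: SimilarityMatrix | np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of the dissimilarity ``1 - r``.

    Returns ``(coords, eigenvalues)``: coordinates (S, dims) from the top
    positive eigencomponents of the double-centred squared-dissimilarity
    matrix (defined up to rotation/reflection) and the full eigenvalue
    spectrum, descending, with negative values reporting non-Euclidean
    structure.
    """
    M = sim.M if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("similarity matrix must be square and symmetric")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    S = D.shape[0]
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((S, dims))
    for k in range(min(dims, S)):
        if evals[k] > 0:
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    return coords, evals


# ---------------------------------------------------------------------------
# pairwise decoding
# ---------------------------------------------------------------------------

def pairwise_decode(
    train_tensor: TrialTensor,
    test_tensor: TrialTensor | None = None,
    pairs: list[tuple[int, int]] | int | None = None,
    n_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
    neuron_mask: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Linear max-margin pairwise stimulus decoding with 5-fold cross-validation.

    Per stimulus pair a linear-kernel SVM (regularisation ``C``) is trained
    on the population vectors of the two stimuli and scored as the fraction
    of correctly classified held-out trials; folds are stratified so each
    trial is tested exactly once.  With ``test_tensor`` the classifier is
    trained on the training day's fold-train trials and tested on the test
    day's fold-test trials (fold-respecting cross-day protocol); the neuron
    set is restricted to neurons present on both days so dimensionality
    matches.  ``pairs`` may be explicit, an integer (random subset of all
    pairs), or None (all pairs).  Returns the mean accuracy and the per-pair
    table.
    """
    mask = train_tensor.present.copy()
    if test_tensor is not None:
        mask &= test_tensor.present
    if neuron_mask is not None:
        mask &= np.asarray(neuron_mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("no neurons available for decoding")
    A_train = train_tensor.A[mask]
    A_test = (test_tensor.A[mask] if test_tensor is not None else A_train)
    N, S, T = A_train.shape
    all_pairs = list(itertools.combinations(range(S), 2))
    rng = np.random.default_rng(child_seed(seed, "decode", train_tensor.fov_id, train_tensor.day))
    if pairs is None:
        use_pairs = all_pairs
    elif isinstance(pairs, int):
        sel = rng.choice(len(all_pairs), size=min(pairs, len(all_pairs)), replace=False)
        use_pairs = [all_pairs[i] for i in sorted(sel)]
    else:
        use_pairs = [tuple(p) for p in pairs]

    rows = []
    y = np.repeat([0, 1], T)
    for s1, s2 in use_pairs:
        X_tr = np.concatenate([A_train[:, s1, :].T, A_train[:, s2, :].T])  # (2T, N)
        X_te = np.concatenate([A_test[:, s1, :].T, A_test[:, s2, :].T])
        ok = np.isfinite(X_tr).all(axis=1) & np.isfinite(X_te).all(axis=1)
        if ok.sum() < 2 * n_folds:
            rows.append((s1, s2, np.nan))
            continue
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=child_seed(seed, "fold", s1, s2))
        correct = total = 0
        Xo, yo = X_tr[ok], y[ok]
        Xe = X_te[ok]
        for tr_idx, te_idx in skf.split(Xo, yo):
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xo[tr_idx], yo[tr_idx])
            pred = clf.predict(Xe[te_idx])
            correct += int((pred == yo[te_idx]).sum())
            total += len(te_idx)
        rows.append((s1, s2, correct / total))
    frame = pd.DataFrame(rows, columns=["s1", "s2", "accuracy"])
    return float(frame["accuracy"].mean()), frame
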