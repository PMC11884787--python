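"""Shared response modeling and cross-participant map transfer.

The shared response model (SRM) expresses each participant's movie-evoked
responses ``X_i`` (units x T) as an orthonormal per-participant basis ``W_i``
(units x k) times a common low-dimensional shared time course ``S`` (k x T):

    minimize  sum_i || X_i - W_i S ||_F^2   subject to  W_i' W_i = I_k.

The deterministic solver alternates an orthogonal Procrustes update of each
basis (``W_i <- U V'`` from the SVD of ``X_i S'``) with the closed-form
shared-response update (``S <- mean_i W_i' X_i``); both steps are exact
minimizers, so the objective never increases.

Map transfer: ground-truth retinotopic maps of the training participants are
projected into the shared space (``v_i = W_i' m_i``) and averaged; a held-out
participant's basis is learned against the frozen shared time course with a
single Procrustes solve, and the group map template is brought into their
brain space as ``W_test v``. Baselines: time-reversing the held-out movie
data (no valid stimulus-locked mapping can be learned) and the anatomical
average of other participants' maps on the common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sheet import GradientLine, GroundTruthMaps
from .simulate import ParticipantRecording, StudyBundle, child_rng
from .stats import (
    BootstrapResult,
    ContractError,
    bootstrap_mean_difference,
    fisher_z,
    pearson_corr,
)
from .ica import score_component

__all__ = [
    "SRM",
    "SRMResults",
    "MapTransferResult",
    "fit_srm",
    "transform_map_to_shared",
    "fit_new_participant",
    "predict_map",
    "flipped_baseline",
    "anatomical_average_baseline",
    "leave_one_out_experiment",
    "select_k_crossval",
    "LeaveOneOutResult",
]

DEFAULT_K = 10  # shared-space dimensionality used throughout the transfer analyses


def _procrustes(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes: argmin_{W'W=I} ||X - W S||_F = U V' of X S'."""
    u, _, vt = np.linalg.svd(x @ s.T, full_matrices=False)
    return u @ vt


@dataclass
class SRMResults:
    """Fitted shared response model.

    ``bases[i]`` is the orthonormal units x k basis of training participant
    i; ``shared_timecourse`` is the k x T shared response; ``objective`` is
    the per-iteration sum of squared residuals (non-increasing).
    """

    k: int
    bases: list[np.ndarray]
    shared_timecourse: np.ndarray
    objective: np.ndarray
    seed: int
    converged: bool
    rank_deficient: bool = False

    @property
    def n_train(self) -> int:
        return len(self.bases)

    def residual(self, data: list[np.ndarray]) -> float:
        """Relative residual ||X - W S|| / ||X|| over the training stack."""
        num = sum(
            float(np.linalg.norm(x - w @ self.shared_timecourse) ** 2)
            for x, w in zip(data, self.bases)
        )
        den = sum(float(np.linalg.norm(x) ** 2) for x in data)
        return float(np.sqrt(num / den)) if den > 0 else 0.0

    def summary(self) -> str:
        lines = ["Shared response model", "=" * 45]
        lines.append(
            f"k = {self.k}   training participants = {self.n_train}   "
            f"T = {self.shared_timecourse.shape[1]}"
        )
        lines.append(
            f"iterations = {len(self.objective)}   converged = {self.converged}"
        )
        lines.append(
            f"objective: {self.objective[0]:.4g} -> {self.objective[-1]:.4g}"
        )
        ortho = max(
            float(np.abs(w.T @ w - np.eye(self.k)).max()) for w in self.bases
        )
        lines.append(f"max basis orthonormality defect: {ortho:.2e}")
        return "\n".join(lines)


class SRM:
    """Deterministic shared response model (Procrustes/averaging alternation).

    Parameters
    ----------
    k : int
        Shared-space dimensionality (default 10).
    max_iter, tol : int, float
        Stop after ``max_iter`` alternations or when the relative objective
        decrease falls below ``tol``.
    seed : int
        Seeds the QR-of-Gaussian basis initialization.
    """

    def __init__(self, k: int = DEFAULT_K, max_iter: int = 50, tol: float = 1e-9, seed: int = 0):
        self.k = int(k)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.seed = int(seed)

    def fit(self, data: list[np.ndarray]) -> SRMResults:
        if len(data) < 1:
            raise ContractError("need at least one training participant")
        t = data[0].shape[1]
        for x in data:
            if x.ndim != 2:
                raise ContractError("each recording must be a 2-D units x T array")
            if x.shape[1] != t:
                raise ContractError("all participants must share the movie length T")
            if x.shape[0] < self.k:
                raise ContractError("need at least k units per participant")
        if t < self.k:
            raise ContractError(f"T = {t} is smaller than k = {self.k}")
        rank_deficient = any(np.linalg.matrix_rank(x) < self.k for x in data)
        rng = child_rng(self.seed, "srm")
        bases = []
        for x in data:
            q, _ = np.linalg.qr(rng.standard_normal((x.shape[0], self.k)))
            bases.append(q)
        shared = np.mean([w.T @ x for w, x in zip(bases, data)], axis=0)
        objective = []
        converged = False
        for _ in range(self.max_iter):
            bases = [_procrustes(x, shared) for x in data]
            shared = np.mean([w.T @ x for w, x in zip(bases, data)], axis=0)
            obj = sum(
                float(np.linalg.norm(x - w @ shared) ** 2)
                for x, w in zip(data, bases)
            )
            if objective and objective[-1] > 0:
                if (objective[-1] - obj) / objective[-1] < self.tol:
                    objective.append(obj)
                    converged = True
                    break
            objective.append(obj)
        return SRMResults(
            k=self.k,
            bases=bases,
            shared_timecourse=shared,
            objective=np.asarray(objective),
            seed=self.seed,
            converged=converged,
            rank_deficient=rank_deficient,
        )


def fit_srm(
    training: list[np.ndarray],
    k: int = DEFAULT_K,
    max_iter: int = 50,
    tol: float = 1e-9,
    seed: int = 0,
) -> SRMResults:
    """Functional wrapper around :class:`SRM` (units x T arrays, equal T)."""
    return SRM(k=k, max_iter=max_iter, tol=tol, seed=seed).fit(training)


def transform_map_to_shared(map_values: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project a per-unit map into the shared space: ``v = W' m``."""
    m = np.asarray(map_values, dtype=float)
    if m.shape[0] != basis.shape[0]:
        raise ContractError("map length does not match basis rows")
    return basis.T @ m


def fit_new_participant(model: SRMResults, data: np.ndarray) -> np.ndarray:
    """Learn a held-out participant's basis against the frozen shared response.

    A single orthogonal Procrustes solve; the shared time course is not
    modified ("the model is learned and frozen before the held-out
    participant's data is considered").
    """
    s = model.shared_timecourse
    if data.shape[1] != s.shape[1]:
        raise ContractError("held-out T does not match the model's shared response")
    return _procrustes(np.asarray(data, dtype=float), s)


def predict_map(model: SRMResults, group_shared_vector: np.ndarray, test_basis: np.ndarray) -> np.ndarray:
    """Map a shared-space template into the test participant: ``m = W v``.

    The inverse of the participant's analysis mapping ``W'`` is ``W`` itself
    because the basis is orthonormal.
    """
    v = np.asarray(group_shared_vector, dtype=float)
    if v.shape[0] != test_basis.shape[1]:
        raise ContractError("shared vector length does not match basis columns")
    return test_basis @ v


def flipped_baseline(recording: ParticipantRecording) -> ParticipantRecording:
    """Time-reverse each movie segment of a recording (all else untouched).

    A null for functional alignment: the reversed data cannot be locked to
    the shared stimulus response. Applying it twice is the identity.
    """
    data = recording.data.copy()
    for s, e in recording.movie_intervals:
        data[:, s:e] = data[:, s:e][:, ::-1]
    return ParticipantRecording(
        data=data,
        tr=recording.tr,
        movie_intervals=recording.movie_intervals,
        motion=recording.motion,
        seed=recording.seed,
        participant=recording.participant,
        loadings=recording.loadings,
        maps=recording.maps,
    )


@dataclass(frozen=True)
class MapTransferResult:
    """Gradient correlations of a predicted map for one held-out participant."""

    participant: int
    movie: int
    map_type: str  # "spatial_frequency" | "meridian"
    corr_real: float
    corr_flipped: float
    corr_anatomical: float
    predicted_map: np.ndarray | None = None


def anatomical_average_baseline(
    other_maps: list[GroundTruthMaps],
    map_type: str,
    truth: np.ndarray,
    lines: list[GradientLine],
) -> tuple[np.ndarray, float]:
    """Element-wise mean of the other participants' maps, scored like SRM.

    The synthetic sheets share coordinates, which plays the role of surface
    template alignment; map jitter in the generator emulates residual
    anatomical misalignment. Returns (average map, signed gradient
    correlation with the held-out truth).
    """
    if not other_maps:
        raise ContractError("need at least one other participant")
    avg = np.mean([m.as_dict()[map_type] for m in other_maps], axis=0)
    return avg, score_component(avg, truth, lines, absolute=False)


@dataclass
class LeaveOneOutResult:
    """Cross-participant map-transfer experiment results."""

    table: pd.DataFrame  # one row per (participant, movie, map_type)
    tests: dict  # e.g. "spatial_frequency:real_vs_flipped" -> BootstrapResult
    k: int

    def mean_corr(self, map_type: str, column: str = "corr_real") -> float:
        rows = self.table[self.table["map_type"] == map_type]
        return float(rows[column].mean())

    def summary(self) -> str:
        lines = ["Shared-response map transfer (leave-one-out)", "=" * 55]
        lines.append(f"k = {self.k}")
        for mt in ("spatial_frequency", "meridian"):
            rows = self.table[self.table["map_type"] == mt]
            if not len(rows):
                continue
            lines.append(
                f"  {mt:<18s} real r = {rows['corr_real'].mean(): .3f}   "
                f"flipped r = {rows['corr_flipped'].mean(): .3f}   "
                f"anatomical r = {rows['corr_anatomical'].mean(): .3f}"
            )
        for name, res in self.tests.items():
            lines.append(
                f"  {name:<40s} dZ = {res.mean_diff: .3f}  p {res.p_label}"
            )
        return "\n".join(lines)


def leave_one_out_experiment(
    bundle: StudyBundle,
    k: int = DEFAULT_K,
    n_boot: int = 10_000,
    seed: int = 0,
    test_participants: list[int] | None = None,
) -> LeaveOneOutResult:
    """Hold out each participant, train the SRM on the rest, transfer maps.

    Per held-out participant and movie: fit the SRM on the training set,
    project the training participants' ground-truth maps into the shared
    space and average, learn the held-out basis against the frozen shared
    response (real and time-flipped), and score the predicted maps by signed
    gradient correlation with the held-out truth. The anatomical-average
    baseline is scored identically. Per-participant Fisher-Z differences
    (averaged across movies within participant) are bootstrap tested.
    """
    if bundle.n_participants < 3:
        raise ContractError("need at least 3 participants")
    line_sets = {
        "spatial_frequency": bundle.lines_parallel,
        "meridian": bundle.lines_perpendicular,
    }
    held = test_participants if test_participants is not None else range(
        bundle.n_participants
    )
    rows = []
    for i in held:
        train = [r for j, r in enumerate(bundle.recordings) if j != i]
        test = bundle.recordings[i]
        test_flip = flipped_baseline(test)
        for movie in range(len(test.movie_intervals)):
            model = fit_srm(
                [r.movie_data(movie) for r in train], k=k, seed=seed
            )
            w_test = fit_new_participant(model, test.movie_data(movie))
            w_flip = fit_new_participant(model, test_flip.movie_data(movie))
            for map_type, lines in line_sets.items():
                truth = test.maps.as_dict()[map_type]
                template = np.mean(
                    [
                        transform_map_to_shared(r.maps.as_dict()[map_type], w)
                        for r, w in zip(train, model.bases)
                    ],
                    axis=0,
                )
                pred = predict_map(model, template, w_test)
                pred_flip = predict_map(model, template, w_flip)
                _, corr_anat = anatomical_average_baseline(
                    [r.maps for r in train], map_type, truth, lines
                )
                rows.append(
                    MapTransferResult(
                        participant=i,
                        movie=movie,
                        map_type=map_type,
                        corr_real=score_component(pred, truth, lines, absolute=False),
                        corr_flipped=score_component(
                            pred_flip, truth, lines, absolute=False
                        ),
                        corr_anatomical=corr_anat,
                    )
                )
    table = pd.DataFrame(
        [
            {
                "participant": r.participant,
                "movie": r.movie,
                "map_type": r.map_type,
                "corr_real": r.corr_real,
                "corr_flipped": r.corr_flipped,
                "corr_anatomical": r.corr_anatomical,
            }
            for r in rows
        ]
    )
    tests = {}
    for mt in table["map_type"].unique():
        sub = table[table["map_type"] == mt]
        for name, a, b in (
            ("real_vs_flipped", "corr_real", "corr_flipped"),
            ("anatomical_vs_real", "corr_anatomical", "corr_real"),
        ):
            diffs = (
                sub.assign(
                    dz=lambda d, a=a, b=b: d[a].map(fisher_z) - d[b].map(fisher_z)
                )
                .groupby("participant")["dz"]
                .mean()  # average across movies within participant first
                .to_numpy()
            )
            if diffs.size >= 2:
                tests[f"{mt}:{name}"] = bootstrap_mean_difference(
                    diffs, n_boot=n_boot, seed=seed
                )
    return LeaveOneOutResult(table=table, tests=tests, k=k)


def select_k_crossval(
    training: list[np.ndarray],
    k_grid: list[int] | None = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the shared-space dimensionality by cross-validated reconstruction.

    Split policy: participant-wise leave-one-out combined with held-out time
    halves. For each k, the SRM is fit on the training participants' first
    time halves; the held-out participant's basis is learned on their first
    half; their second half is reconstructed from the training participants'
    second-half shared response and scored by correlation. When no grid is
    given the default dimensionality of 10 is returned without search.
    """
    if k_grid is not None and len(k_grid) == 0:
        raise ContractError("k grid must not be empty")
    if k_grid is None:
        return DEFAULT_K, pd.DataFrame(columns=["k", "score"])
    if len(training) < 3:
        raise ContractError("need at least 3 participants")
    t = training[0].shape[1]
    half = t // 2
    scores = []
    for k in k_grid:
        per_holdout = []
        for i in range(len(training)):
            train1 = [x[:, :half] for j, x in enumerate(training) if j != i]
            train2 = [x[:, half:] for j, x in enumerate(training) if j != i]
            model = fit_srm(train1, k=k, seed=seed)
            s2 = np.mean(
                [w.T @ x for w, x in zip(model.bases, train2)], axis=0
            )
            w_i = fit_new_participant(model, training[i][:, :half])
            pred = w_i @ s2
            actual = training[i][:, half:]
            per_holdout.append(pearson_corr(pred.ravel(), actual.ravel()))
        scores.append({"k": int(k), "score": float(np.mean(per_holdout))})
    curve = pd.DataFrame(scores)
    best = int(curve.loc[curve["score"].idxmax(), "k"])
    return best, curve
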