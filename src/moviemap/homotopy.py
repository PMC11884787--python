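"""Cross-hemisphere homotopic correlation analysis.

Functional activity is averaged within each visual area and each hemisphere,
then every left-hemisphere area time course is Pearson correlated with every
right-hemisphere area time course, giving a left-by-right matrix that is not
diagonally symmetric. Matrix cells are grouped by area metadata:

* same area, same stream (homotopic; e.g. left ventral V1 - right ventral V1)
* same area, opposite stream (e.g. left ventral V1 - right dorsal V1)
* adjacent within stream (hierarchy distance 1; e.g. ventral V1 - ventral V2)
* distal within stream (hierarchy distance >= 2; e.g. ventral V1 - hV4)

Both asymmetric cells of each heterotopic pair enter their group. Cell
groups are averaged on Fisher-Z values within participant and the
per-participant differences between groups are tested by participant
bootstrap. A motion regressor can be partialled out of every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .sheet import CorticalSheet
from .simulate import ParticipantRecording, StudyBundle
from .stats import (
    BootstrapResult,
    ContractError,
    MDSEmbedding,
    bootstrap_mean_difference,
    fisher_z,
    inverse_fisher_z,
    mds_embed,
    partial_corr,
    pearson_corr,
)

__all__ = [
    "AreaTimecourseSet",
    "CrossHemisphereMatrix",
    "HomotopyContrasts",
    "CONTRAST_NAMES",
    "extract_area_timecourses",
    "cross_hemisphere_matrix",
    "homotopy_contrasts",
    "group_contrast_test",
    "mds_of_group_matrix",
    "HomotopyAnalysis",
    "HomotopyResults",
]

GROUP_NAMES = (
    "same_area_same_stream",
    "same_area_cross_stream",
    "adjacent_same_stream",
    "distal_same_stream",
)
CONTRAST_NAMES = ("same_vs_cross", "same_vs_adjacent", "adjacent_vs_distal")
#: contrast -> (minuend group, subtrahend group)
CONTRAST_DEFS = {
    "same_vs_cross": ("same_area_same_stream", "same_area_cross_stream"),
    "same_vs_adjacent": ("same_area_same_stream", "adjacent_same_stream"),
    "adjacent_vs_distal": ("adjacent_same_stream", "distal_same_stream"),
}


@dataclass(frozen=True)
class AreaTimecourseSet:
    """Mean time course per (hemisphere, area), with area ordering metadata."""

    timecourses: dict  # (hemi, area) -> (T,) array
    stream: dict  # area -> "ventral"/"dorsal"
    level: dict  # area -> hierarchy level (V1=1 ... )

    def areas(self, hemi: str) -> list[str]:
        return [a for (h, a) in self.timecourses if h == hemi]


def extract_area_timecourses(
    recording: ParticipantRecording, sheet: CorticalSheet
) -> AreaTimecourseSet:
    """Unweighted mean time course across the member units of each area."""
    if recording.n_units != sheet.n_units:
        raise ContractError("recording units do not align with sheet units")
    tcs: dict = {}
    meta = sheet.area_meta()
    for hemi in ("left", "right"):
        for spec in sheet.areas:
            idx = sheet.area_indices(spec.name, hemi)
            if idx.size == 0:
                continue  # missing areas are ignored in the analyses
            tcs[(hemi, spec.name)] = recording.data[idx].mean(axis=0)
    return AreaTimecourseSet(
        timecourses=tcs,
        stream={a: meta[a].stream for a in meta},
        level={a: meta[a].level for a in meta},
    )


@dataclass(frozen=True)
class CrossHemisphereMatrix:
    """Left-areas x right-areas Pearson correlations with area metadata."""

    values: pd.DataFrame  # index: left areas, columns: right areas
    stream: dict
    level: dict


def cross_hemisphere_matrix(
    tcs: AreaTimecourseSet, confounds=None
) -> CrossHemisphereMatrix:
    """Correlate every left-hemisphere area with every right-hemisphere area.

    With ``confounds`` (e.g. a motion regressor), each cell is the partial
    correlation controlling for the confounds.
    """
    left = tcs.areas("left")
    right = tcs.areas("right")
    if not left or not right:
        raise ContractError("both hemispheres must contribute at least one area")
    mat = np.empty((len(left), len(right)))
    for i, la in enumerate(left):
        for j, ra in enumerate(right):
            x = tcs.timecourses[("left", la)]
            y = tcs.timecourses[("right", ra)]
            if confounds is None:
                mat[i, j] = pearson_corr(x, y)
            else:
                mat[i, j] = partial_corr(x, y, confounds)
    return CrossHemisphereMatrix(
        values=pd.DataFrame(mat, index=left, columns=right),
        stream=dict(tcs.stream),
        level=dict(tcs.level),
    )


@dataclass(frozen=True)
class HomotopyContrasts:
    """Fisher-Z cell-group means and their differences for one participant.

    ``group_z`` holds the Fisher-Z mean of each cell group (NaN when the
    group has no cells); ``group_r`` the same means converted back to
    correlation units for display; ``delta`` the contrast differences in
    Fisher-Z units.
    """

    group_z: dict
    group_r: dict
    delta: dict

    def available(self, contrast: str) -> bool:
        a, b = CONTRAST_DEFS[contrast]
        return not (np.isnan(self.group_z[a]) or np.isnan(self.group_z[b]))


def _cell_group(matrix: CrossHemisphereMatrix, la: str, ra: str) -> str | None:
    same_stream = matrix.stream[la] == matrix.stream[ra]
    dist = abs(matrix.level[la] - matrix.level[ra])
    if dist == 0:
        return "same_area_same_stream" if same_stream else "same_area_cross_stream"
    if same_stream:
        return "adjacent_same_stream" if dist == 1 else "distal_same_stream"
    return None  # cross-stream, different level: not used by any contrast


def homotopy_contrasts(matrix: CrossHemisphereMatrix) -> HomotopyContrasts:
    """Group matrix cells by area metadata and average on the Fisher-Z scale."""
    groups: dict[str, list[float]] = {g: [] for g in GROUP_NAMES}
    for la in matrix.values.index:
        for ra in matrix.values.columns:
            g = _cell_group(matrix, la, ra)
            if g is not None:
                groups[g].append(fisher_z(matrix.values.loc[la, ra]))
    group_z = {
        g: (float(np.mean(v)) if v else float("nan")) for g, v in groups.items()
    }
    group_r = {
        g: (inverse_fisher_z(z) if not np.isnan(z) else float("nan"))
        for g, z in group_z.items()
    }
    delta = {
        name: group_z[a] - group_z[b] for name, (a, b) in CONTRAST_DEFS.items()
    }
    return HomotopyContrasts(group_z=group_z, group_r=group_r, delta=delta)


def group_contrast_test(
    contrasts: list[HomotopyContrasts],
    which: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Participant bootstrap of one contrast's per-participant Fisher-Z differences."""
    if which not in CONTRAST_DEFS:
        raise ContractError(f"unknown contrast: {which!r}")
    diffs = [c.delta[which] for c in contrasts if c.available(which)]
    if len(diffs) < 2:
        raise ContractError("need at least 2 participants with this contrast")
    return bootstrap_mean_difference(diffs, n_boot=n_boot, seed=seed)


def mds_of_group_matrix(
    matrices: list[CrossHemisphereMatrix], seed: int = 0
) -> tuple[MDSEmbedding, float]:
    """2-D MDS of the participant-average matrix, plus a stream silhouette.

    The matrices are averaged element-wise, each left-hemisphere area's row
    is treated as a feature vector, pairwise Euclidean distances between
    rows form the dissimilarity matrix, and the resulting 2-D embedding is
    scored by the silhouette of the dorsal/ventral labels (positive =
    streams separate).
    """
    if not matrices:
        raise ContractError("need at least one matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if list(m.values.index) != list(ref.values.index) or list(
            m.values.columns
        ) != list(ref.values.columns):
            raise ContractError("matrices must share the same area scheme")
    avg = np.mean([m.values.to_numpy() for m in matrices], axis=0)
    rows = avg
    diff = rows[:, None, :] - rows[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 0.0)
    emb = mds_embed(dist, n_dims=2, seed=seed)
    labels = [ref.stream[a] for a in ref.values.index]
    sil = float("nan")
    if len(set(labels)) == 2:
        sil = float(silhouette_score(emb.coordinates, labels))
    return emb, sil


@dataclass
class HomotopyResults:
    """Fitted homotopy analysis: matrices, contrasts, and bootstrap tests."""

    matrices: list[CrossHemisphereMatrix]
    contrasts: list[HomotopyContrasts]
    tests: dict  # contrast name -> BootstrapResult
    group_matrix: pd.DataFrame
    n_boot: int
    seed: int
    embedding: MDSEmbedding | None = None
    stream_silhouette: float = float("nan")

    def group_means_r(self) -> pd.Series:
        """Group means (Fisher-Z averaged, reported as correlations)."""
        out = {}
        for g in GROUP_NAMES:
            zs = [c.group_z[g] for c in self.contrasts if not np.isnan(c.group_z[g])]
            out[g] = inverse_fisher_z(float(np.mean(zs))) if zs else float("nan")
        return pd.Series(out, name="mean_r")

    def summary(self) -> str:
        lines = ["Homotopy analysis", "=" * 55]
        means = self.group_means_r()
        lines.append(f"participants: {len(self.contrasts)}   n_boot: {self.n_boot}")
        lines.append("-" * 55)
        lines.append("cell-group means (correlation units):")
        for g, r in means.items():
            lines.append(f"  {g:<24s} r = {r: .3f}")
        lines.append("-" * 55)
        lines.append("contrasts (Fisher-Z difference, participant bootstrap):")
        for name, res in self.tests.items():
            lines.append(
                f"  {name:<20s} dZ = {res.mean_diff: .3f}  "
                f"CI [{res.ci_low: .3f}, {res.ci_high: .3f}]  p {res.p_label}"
            )
        if self.embedding is not None:
            lines.append("-" * 55)
            lines.append(
                f"MDS: stress-1 = {self.embedding.stress:.3f}, "
                f"stream silhouette = {self.stream_silhouette:.3f}"
            )
        return "\n".join(lines)

    def plot_matrix(self, ax=None):
        """Heatmap of the participant-average left x right correlation matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(self.group_matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.group_matrix.columns)))
        ax.set_xticklabels(self.group_matrix.columns, rotation=90)
        ax.set_yticks(range(len(self.group_matrix.index)))
        ax.set_yticklabels(self.group_matrix.index)
        ax.set_xlabel("right hemisphere")
        ax.set_ylabel("left hemisphere")
        ax.figure.colorbar(im, ax=ax, label="r")
        return ax


class HomotopyAnalysis:
    """Cross-hemisphere homotopy model over a cohort of recordings.

    Parameters
    ----------
    bundle : StudyBundle
        Cohort with sheet and recordings.
    control_motion : bool
        Partial out each participant's motion regressor from every cell.
    run_mds : bool
        Also embed the participant-average matrix in 2-D.
    """

    def __init__(
        self,
        bundle: StudyBundle,
        control_motion: bool = False,
        run_mds: bool = False,
    ):
        self.bundle = bundle
        self.control_motion = control_motion
        self.run_mds = run_mds

    def fit(self, n_boot: int = 10_000, seed: int = 0) -> HomotopyResults:
        matrices, contrasts = [], []
        for rec in self.bundle.recordings:
            tcs = extract_area_timecourses(rec, self.bundle.sheet)
            conf = rec.motion if self.control_motion else None
            mat = cross_hemisphere_matrix(tcs, confounds=conf)
            matrices.append(mat)
            contrasts.append(homotopy_contrasts(mat))
        tests = {
            name: group_contrast_test(contrasts, name, n_boot=n_boot, seed=seed + k)
            for k, name in enumerate(CONTRAST_NAMES)
        }
        group = pd.DataFrame(
            np.mean([m.values.to_numpy() for m in matrices], axis=0),
            index=matrices[0].values.index,
            columns=matrices[0].values.columns,
        )
        res = HomotopyResults(
            matrices=matrices,
            contrasts=contrasts,
            tests=tests,
            group_matrix=group,
            n_boot=n_boot,
            seed=seed,
        )
        if self.run_mds:
            emb, sil = mds_of_group_matrix(matrices, seed=seed)
            res.embedding = emb
            res.stream_silhouette = sil
        return res
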