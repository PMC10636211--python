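"""Per-individual presence/absence calling of EVE loci from read depth.

A locus is called present in an individual when its mean sequencing depth
exceeds the profile's depth threshold AND more than half of its positions
are covered by at least one read.  Two profiles mirror the study design:
``strict`` (depth > 5, for cohorts sequenced deep enough to be held to a
15x genome-wide QC bar) and ``relaxed`` (depth > 1, genome-wide bar 5x,
for shallower cohorts).  All comparisons are strict inequalities
("greater than" / "higher than"), so boundary values fall on the
absent/excluded side.

"Coverage" at locus level is interpreted as breadth of coverage at
depth >= 1 (the fraction of positions with any read), which the source
protocol leaves undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .catalog import EveLocus
from .io import GenomeAssembly, ReadPlacement

PROFILES = {"strict": {"locus_depth": 5.0, "individual_depth": 15.0},
            "relaxed": {"locus_depth": 1.0, "individual_depth": 5.0}}
WINDOW_NT = 100


@dataclass
class DepthProfile:
    individual_id: str
    locus_id: str
    depth: np.ndarray  # per-base depth over the locus
    window_nt: int = WINDOW_NT

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    @property
    def covered_fraction(self) -> float:
        return float((self.depth >= 1).mean())

    @property
    def window_depths(self) -> list[tuple[int, int, float]]:
        """(window_start, window_width, mean depth) per non-overlapping tile;
        the trailing partial window is reported at its actual width."""
        out = []
        L = len(self.depth)
        for s in range(0, L, self.window_nt):
            w = min(self.window_nt, L - s)
            out.append((s, w, float(self.depth[s:s + w].mean())))
        return out


@dataclass(frozen=True)
class PresenceCall:
    individual_id: str
    locus_id: str
    present: bool
    profile_used: str
    mean_depth: float
    covered_fraction: float


@dataclass(frozen=True)
class IndividualQC:
    individual_id: str
    genome_wide_mean_depth: float
    included: bool
    min_depth_required: float


def depth_profile(
    placements: list[ReadPlacement], locus: EveLocus, individual_id: str | None = None
) -> DepthProfile:
    """Per-base depth over the locus from read placements.

    Multi-mapped placements each count once per placement (multi-mapped
    reads are retained for depth).  Empty placements give an all-zero
    profile.
    """
    L = locus.length_nt
    if L <= 0:
        raise ValueError("zero-length locus")
    diff = np.zeros(L + 1, dtype=np.int64)
    ind = individual_id
    for p in placements:
        if p.contig_id != locus.contig_id:
            continue
        if ind is not None and p.individual_id != ind:
            continue
        lo = max(p.start, locus.start) - locus.start
        hi = min(p.end, locus.end) - locus.start
        if hi > lo:
            diff[lo] += 1
            diff[hi] -= 1
    depth = np.cumsum(diff[:-1])
    if ind is None:
        inds = {p.individual_id for p in placements}
        ind = inds.pop() if len(inds) == 1 else "all"
    return DepthProfile(ind, locus.locus_id, depth)


def qc_individual(
    placements: list[ReadPlacement], genome: GenomeAssembly, profile: str = "strict",
    individual_id: str | None = None,
) -> IndividualQC:
    """Genome-wide mean-depth QC: individuals below the profile's bar
    (15.0x strict, 5.0x relaxed; the bar itself is included) are excluded."""
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {sorted(PROFILES)}")
    min_depth = PROFILES[profile]["individual_depth"]
    total = genome.total_length
    ind = individual_id
    if ind is None:
        inds = {p.individual_id for p in placements}
        ind = inds.pop() if len(inds) == 1 else "all"
    aligned = sum(
        p.length for p in placements
        if individual_id is None or p.individual_id == individual_id
    )
    mean = aligned / total if total else 0.0
    return IndividualQC(ind, mean, mean >= min_depth, min_depth)


def call_presence(profile: DepthProfile, criteria: str = "strict") -> PresenceCall:
    """Present iff mean depth > threshold (5 strict / 1 relaxed) and covered
    fraction > 0.5; both inequalities strict."""
    if criteria not in PROFILES:
        raise ValueError(f"criteria must be one of {sorted(PROFILES)}")
    if len(profile.depth) == 0:
        raise ValueError("zero-length locus")
    thr = PROFILES[criteria]["locus_depth"]
    md = profile.mean_depth
    cf = profile.covered_fraction
    return PresenceCall(profile.individual_id, profile.locus_id,
                        md > thr and cf > 0.5, criteria, md, cf)


def presence_matrix(calls: list[PresenceCall]) -> pd.DataFrame:
    """Individuals x loci 0/1 matrix."""
    rows = sorted({c.individual_id for c in calls})
    cols = sorted({c.locus_id for c in calls})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for c in calls:
        mat.loc[c.individual_id, c.locus_id] = int(c.present)
    mat.index.name = "individual"
    return mat


def covered_fraction_matrix(calls: list[PresenceCall]) -> pd.DataFrame:
    rows = sorted({c.individual_id for c in calls})
    cols = sorted({c.locus_id for c in calls})
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for c in calls:
        mat.loc[c.individual_id, c.locus_id] = c.covered_fraction
    mat.index.name = "individual"
    return mat


@dataclass
class PcaResult:
    scores: pd.DataFrame  # individuals x components
    loadings: pd.DataFrame  # loci x components
    explained_variance_ratio: np.ndarray


def presence_matrix_pca(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """PCA of the (column-centered) presence or covered-fraction matrix via
    singular value decomposition; missing entries are not allowed (impute 0
    for absent individuals upstream)."""
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing entries")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
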