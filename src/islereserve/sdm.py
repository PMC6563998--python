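"""Climate-suitability models, repeated-split TSS evaluation, consensus projection.

The modelling procedure mirrors standard ensemble SDM practice on
presence-only atlas data:

1. presences are complemented with an equal number of pseudo-absence
   (background) cells drawn uniformly from island cells without presences;
2. each candidate model is evaluated over ten random 80/20
   calibration/validation splits with the True Skill Statistic
   (TSS = sensitivity + specificity - 1);
3. members whose mean TSS is below zero are discarded, survivors are refit
   on the full data and combined by majority vote: a cell is present in the
   consensus iff at least half of the retained members predict presence.

Two reference model families stand behind the pluggable interface: a
rectilinear climate envelope (per-covariate min/max box over calibration
presences) and a standardized-distance niche centroid thresholded at the
largest calibration distance (zero omission on training presences).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import BinaryGrid, Grid, StudyArea, require_aligned

__all__ = [
    "ClimateStack",
    "OccurrenceSet",
    "TSSResult",
    "EnvelopeModel",
    "CentroidModel",
    "EnsembleResult",
    "MIN_OCCURRENCES",
    "TooFewOccurrencesError",
    "EmptyEnsembleError",
    "sample_background",
    "generate_splits",
    "fit_suitability_model",
    "compute_tss",
    "ensemble_consensus",
    "fit_ensemble",
]

#: Minimum number of presence records required to model a species
#: (five points per climatic variable, three variables).
MIN_OCCURRENCES = 15

COVARIATES = ("tmax", "ppmin", "prange")


class TooFewOccurrencesError(ValueError):
    """A species does not meet the occurrence floor for modelling."""


class EmptyEnsembleError(RuntimeError):
    """Every candidate member was discarded by the TSS filter."""


@dataclasses.dataclass
class ClimateStack:
    """The three climatic covariates for one period, mutually aligned.

    tmax: maximum annual temperature (degC); ppmin: minimum annual
    precipitation (mm); prange: annual range of precipitation (mm).
    """

    tmax: Grid
    ppmin: Grid
    prange: Grid
    period_label: str = ""

    def __post_init__(self) -> None:
        require_aligned(self.tmax, self.ppmin, self.prange)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmax.values.shape

    def matrix(self) -> np.ndarray:
        """(n_cells_total, 3) covariate matrix in row-major cell order."""
        return np.column_stack(
            [self.tmax.values.ravel(), self.ppmin.values.ravel(), self.prange.values.ravel()]
        )

    def at(self, cells: np.ndarray) -> np.ndarray:
        """(len(cells), 3) covariates at flat cell indices."""
        return self.matrix()[np.asarray(cells, dtype=int)]


@dataclasses.dataclass
class OccurrenceSet:
    """Presence and background records for one species, as flat cell indices."""

    species_id: str
    presence_cells: np.ndarray
    background_cells: np.ndarray

    def __post_init__(self) -> None:
        self.presence_cells = np.unique(np.asarray(self.presence_cells, dtype=int))
        self.background_cells = np.unique(np.asarray(self.background_cells, dtype=int))

    @property
    def n_presences(self) -> int:
        return int(self.presence_cells.size)


@dataclasses.dataclass(frozen=True)
class TSSResult:
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def sample_background(
    presence_cells: np.ndarray, area: StudyArea, seed: int, n: int | None = None
) -> np.ndarray:
    """Draw pseudo-absence cells uniformly from island cells without presences.

    Count defaults to the number of presences (prevalence 0.5).
    """
    presence_cells = np.asarray(presence_cells, dtype=int)
    island = np.flatnonzero(area.cells.ravel())
    candidates = np.setdiff1d(island, presence_cells)
    n = presence_cells.size if n is None else n
    n = min(n, candidates.size)  # very widespread species: take all that remain
    if n == 0:
        raise ValueError("no background candidates: species occupies the whole island")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(candidates, size=n, replace=False))


def generate_splits(
    occ: OccurrenceSet,
    n_splits: int = 10,
    calib_fraction: float = 0.8,
    seed: int = 0,
    min_occurrences: int = MIN_OCCURRENCES,
):
    """Random calibration/validation splits of a species' records.

    Presences and backgrounds are split at the same fraction so both classes
    appear in every validation set. Each split partitions the records
    disjointly; the same seed reproduces the same splits. Species below the
    occurrence floor are refused.
    """
    if not 0.0 < calib_fraction < 1.0:
        raise ValueError("calib_fraction must lie strictly between 0 and 1")
    if occ.n_presences < min_occurrences:
        raise TooFewOccurrencesError(
            f"species {occ.species_id!r} has {occ.n_presences} presences; "
            f"at least {min_occurrences} are required"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        calib_idx: list[np.ndarray] = []
        valid_idx: list[np.ndarray] = []
        for cells in (occ.presence_cells, occ.background_cells):
            n_cal = round(calib_fraction * cells.size)
            n_cal = min(max(n_cal, 1), cells.size - 1) if cells.size > 1 else n_cal
            perm = rng.permutation(cells.size)
            calib_idx.append(cells[perm[:n_cal]])
            valid_idx.append(cells[perm[n_cal:]])
        calib = (calib_idx[0], calib_idx[1])
        valid = (valid_idx[0], valid_idx[1])
        splits.append((calib, valid))
    return splits


# ---------------------------------------------------------------------------
# Suitability models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnvelopeModel:
    """Rectilinear climate envelope: presence iff every covariate lies inside
    the [min, max] box spanned by the calibration presences."""

    kind = "envelope"
    lower: np.ndarray
    upper: np.ndarray

    def predict_cells(self, covariates: np.ndarray) -> np.ndarray:
        return np.all((covariates >= self.lower) & (covariates <= self.upper), axis=1)

    def predict(self, climate: ClimateStack) -> BinaryGrid:
        inside = self.predict_cells(climate.matrix()).reshape(climate.shape)
        ref = climate.tmax
        vals = np.where(ref.nodata_mask, 0.0, inside.astype(float))
        return BinaryGrid(
            values=vals,
            nodata_mask=ref.nodata_mask.copy(),
            cellsize=ref.cellsize,
            origin=ref.origin,
            nodata_value=ref.nodata_value,
        )


@dataclasses.dataclass
class CentroidModel:
    """Niche-centroid model: standardized Euclidean distance to the presence
    centroid, thresholded at the largest distance seen among calibration
    presences (zero omission on training data)."""

    kind = "centroid"
    center: np.ndarray
    scale: np.ndarray
    threshold: float

    def distance(self, covariates: np.ndarray) -> np.ndarray:
        z = (covariates - self.center) / self.scale
        return np.sqrt((z**2).sum(axis=1))

    def predict_cells(self, covariates: np.ndarray) -> np.ndarray:
        return self.distance(covariates) <= self.threshold

    def predict(self, climate: ClimateStack) -> BinaryGrid:
        inside = self.predict_cells(climate.matrix()).reshape(climate.shape)
        ref = climate.tmax
        vals = np.where(ref.nodata_mask, 0.0, inside.astype(float))
        return BinaryGrid(
            values=vals,
            nodata_mask=ref.nodata_mask.copy(),
            cellsize=ref.cellsize,
            origin=ref.origin,
            nodata_value=ref.nodata_value,
        )


MODEL_KINDS = ("envelope", "centroid")


def fit_suitability_model(kind: str, presence_cells: np.ndarray, climate: ClimateStack):
    """Fit a reference suitability model on calibration presences."""
    presence_cells = np.asarray(presence_cells, dtype=int)
    if presence_cells.size == 0:
        raise ValueError("calibration set is empty")
    x = climate.at(presence_cells)
    if kind == "envelope":
        return EnvelopeModel(lower=x.min(axis=0), upper=x.max(axis=0))
    if kind == "centroid":
        if presence_cells.size < 2:
            raise ValueError("centroid model requires at least 2 presences")
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        z = (x - center) / scale
        threshold = float(np.sqrt((z**2).sum(axis=1)).max())
        return CentroidModel(center=center, scale=scale, threshold=threshold)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Evaluation and consensus
# ---------------------------------------------------------------------------

def compute_tss(predicted: np.ndarray, observed: np.ndarray) -> TSSResult:
    """True Skill Statistic for binary predictions.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    tss = sensitivity + specificity - 1 in [-1, 1].
    """
    predicted = np.asarray(predicted).astype(bool)
    observed = np.asarray(observed).astype(bool)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length and non-empty")
    n_pos = int(observed.sum())
    n_neg = int((~observed).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("observed labels contain a single class; TSS is undefined")
    tp = int((predicted & observed).sum())
    tn = int((~predicted & ~observed).sum())
    return TSSResult(sensitivity=tp / n_pos, specificity=tn / n_neg)


def consensus_votes(votes: np.ndarray) -> np.ndarray:
    """Majority rule over member predictions: present iff the number of
    members voting presence is at least half the member count.

    ``votes``: (n_members, ...) boolean array.
    """
    votes = np.asarray(votes, dtype=bool)
    n = votes.shape[0]
    return votes.sum(axis=0) >= n / 2.0


def ensemble_consensus(members, climate: ClimateStack) -> BinaryGrid:
    """Project retained members and combine them by majority vote.

    ``members``: list of (model, mean_tss). Members with mean TSS < 0 are
    discarded first; an empty retained set is an error.
    """
    if not members:
        raise ValueError("ensemble has no members")
    retained = [m for m, tss in members if tss >= 0.0]
    if not retained:
        raise EmptyEnsembleError("all ensemble members were discarded (mean TSS < 0)")
    votes = np.stack([m.predict(climate).presence for m in retained])
    present = consensus_votes(votes)
    ref = climate.tmax
    return BinaryGrid(
        values=np.where(ref.nodata_mask, 0.0, present.astype(float)),
        nodata_mask=ref.nodata_mask.copy(),
        cellsize=ref.cellsize,
        origin=ref.origin,
        nodata_value=ref.nodata_value,
    )


@dataclasses.dataclass
class EnsembleResult:
    """Fitted ensemble for one species: members with per-split TSS scores,
    the retained subset, and per-period consensus maps."""

    species_id: str
    member_kinds: list
    split_tss: dict          # kind -> list of per-split tss
    mean_tss: dict           # kind -> float
    retained: list           # fitted models (full-data refit), TSS >= 0
    retained_kinds: list
    consensus: dict          # period_label -> BinaryGrid

    def project(self, climate: ClimateStack) -> BinaryGrid:
        """Project the retained ensemble onto a new climate without refitting."""
        grid = ensemble_consensus([(m, 0.0) for m in self.retained], climate)
        self.consensus[climate.period_label] = grid
        return grid


def fit_ensemble(
    occ: OccurrenceSet,
    climate: ClimateStack,
    kinds=MODEL_KINDS,
    n_splits: int = 10,
    calib_fraction: float = 0.8,
    seed: int = 0,
    min_occurrences: int = MIN_OCCURRENCES,
) -> EnsembleResult:
    """Run the full per-species procedure: split, fit, score with TSS,
    filter, refit on all data, and build the baseline consensus.

    Member scores are the mean TSS across the splits; the retained models
    are refit on the complete presence set so projection to other periods
    reuses identical parameters.
    """
    splits = generate_splits(occ, n_splits, calib_fraction, seed, min_occurrences)
    split_tss: dict[str, list[float]] = {k: [] for k in kinds}
    for (calib_p, _calib_b), (valid_p, valid_b) in splits:
        vcells = np.concatenate([valid_p, valid_b])
        observed = np.concatenate(
            [np.ones(valid_p.size, bool), np.zeros(valid_b.size, bool)]
        )
        for kind in kinds:
            model = fit_suitability_model(kind, calib_p, climate)
            predicted = model.predict_cells(climate.at(vcells))
            split_tss[kind].append(compute_tss(predicted, observed).tss)
    mean_tss = {k: float(np.mean(v)) for k, v in split_tss.items()}
    retained_kinds = [k for k in kinds if mean_tss[k] >= 0.0]
    if not retained_kinds:
        raise EmptyEnsembleError(
            f"species {occ.species_id!r}: every member has mean TSS < 0"
        )
    retained = [
        fit_suitability_model(k, occ.presence_cells, climate) for k in retained_kinds
    ]
    consensus = ensemble_consensus([(m, 0.0) for m in retained], climate)
    return EnsembleResult(
        species_id=occ.species_id,
        member_kinds=list(kinds),
        split_tss=split_tss,
        mean_tss=mean_tss,
        retained=retained,
        retained_kinds=retained_kinds,
        consensus={climate.period_label: consensus},
    )
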