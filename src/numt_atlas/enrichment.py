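"""Permutation enrichment, mtDNA-region enrichment, deletion correlation,
nearest-feature distances and the chromosome-count regression.

The permutation null matches random positions to the observed NUMTs by
count and chromosome (uniform placement along each chromosome, mt contig
and Y excluded); with fixed 200 bp flanks (±100 bp) no length matching is
needed. Two-tailed empirical p values use the add-one rule,
p = min(1, 2·(1 + #as-or-more-extreme)/(N + 1)), so p is never zero and
doubling never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .formats_io import IntervalTrack, ReferenceGenome

FLANK_BP = 100
DEFAULT_PERMUTATIONS = 1000
Y_NAMES = {"chrY", "Y"}


class ConfigurationError(ValueError):
    pass


@dataclass
class PermutationResult:
    track: str
    observed: int
    null_counts: np.ndarray
    empirical_p: float
    direction: str  # enriched | depleted
    seed: int
    n_numts: int


def _merged_arrays(track: IntervalTrack, contig: str) -> tuple[np.ndarray, np.ndarray]:
    merged: list[list[int]] = []
    for iv in track.by_contig(contig):
        s, e = iv[1], iv[2]
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _flanks_overlap(
    positions: np.ndarray, starts: np.ndarray, ends: np.ndarray, flank: int
) -> np.ndarray:
    """Boolean: does [pos - flank, pos + flank] intersect any track interval."""
    if starts.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    a = positions - flank
    b = positions + flank + 1  # half-open
    j = np.searchsorted(ends, a, side="right")
    valid = j < starts.size
    out = np.zeros(positions.shape, dtype=bool)
    out[valid] = starts[j[valid]] < b[valid]
    return out


def permutation_enrichment(
    numt_positions: Sequence[tuple[str, int]],
    track: IntervalTrack,
    reference: ReferenceGenome,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    flank: int = FLANK_BP,
) -> PermutationResult:
    """Two-tailed permutation test of NUMT-flank overlap with a track.

    ``numt_positions`` are (contig, 1-based breakpoint position) per NUMT.
    Each null replicate places the same number of points uniformly on the
    same chromosome as the corresponding observed NUMT.
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    if not track.intervals:
        return PermutationResult(track.name, 0, np.empty(0, dtype=int),
                                 float("nan"), "undefined", seed, 0)
    usable = [
        (c, p) for c, p in numt_positions
        if c != reference.mt_name and c not in Y_NAMES
    ]
    rng = np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_permutations, dtype=np.int64)
    by_contig: dict[str, list[int]] = {}
    for c, p in usable:
        by_contig.setdefault(c, []).append(p)
    for contig, plist in sorted(by_contig.items()):
        starts, ends = _merged_arrays(track, contig)
        pos0 = np.asarray(plist, dtype=np.int64) - 1
        observed += int(_flanks_overlap(pos0, starts, ends, flank).sum())
        L = len(reference.contigs[contig])
        draws = rng.integers(0, L, size=(n_permutations, len(plist)))
        null += _flanks_overlap(draws, starts, ends, flank).sum(axis=1)
    return _permutation_p(track.name, observed, null, seed, len(usable))


def _permutation_p(
    name: str, observed: float, null: np.ndarray, seed: int, n_numts: int
) -> PermutationResult:
    n = len(null)
    mean_null = float(null.mean()) if n else float("nan")
    if observed >= mean_null:
        direction = "enriched"
        extreme = int((null >= observed).sum())
    else:
        direction = "depleted"
        extreme = int((null <= observed).sum())
    p = min(1.0, 2 * (1 + extreme) / (n + 1))
    return PermutationResult(name, int(observed), null, p, direction, seed, n_numts)


# ---------------------------------------------------------------------------
# mtDNA regions


def load_mt_regions(path: Optional[str] = None) -> pd.DataFrame:
    """Packaged (or user-supplied) mt region table.

    Columns: name, start, end (1-based inclusive; start > end means the
    region crosses the circular origin), strand, kind.
    """
    if path is None:
        path = str(resources.files("numt_atlas").joinpath("data/mt_regions.tsv"))
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["name", "start", "end", "strand", "kind"],
    )
    _require_regions(df)
    return df


def _require_regions(df: pd.DataFrame) -> None:
    required = {"D-loop", "HV1", "HV2", "HV3", "OH", "OL"}
    missing = required - set(df["name"])
    if missing:
        raise ConfigurationError(f"mt region table missing {sorted(missing)}")


def _region_membership(
    positions: np.ndarray, start: int, end: int, mt_length: int
) -> np.ndarray:
    """1-based positions inside a possibly origin-crossing region."""
    if start <= end:
        return (positions >= start) & (positions <= end)
    return (positions >= start) | (positions <= end)


def mt_region_enrichment(
    mt_breakpoints: Sequence[int],
    mt_length: int,
    regions: Optional[pd.DataFrame] = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    combine_trna: bool = True,
) -> dict[str, PermutationResult]:
    """Per-region permutation enrichment of mt breakpoint positions.

    The null draws the same number of positions uniformly on the circular
    mt genome. The 22 tRNA genes are combined into one "tRNA" region set.
    """
    if regions is None:
        regions = load_mt_regions()
    else:
        _require_regions(regions)
    pos = np.asarray(list(mt_breakpoints), dtype=np.int64)
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, mt_length + 1, size=(n_permutations, len(pos)))
    results: dict[str, PermutationResult] = {}
    items: list[tuple[str, list[tuple[int, int]]]] = []
    trna_rows = regions[regions["kind"] == "tRNA"]
    for _, row in regions.iterrows():
        if combine_trna and row["kind"] == "tRNA":
            continue
        items.append((row["name"], [(int(row["start"]), int(row["end"]))]))
    if combine_trna and len(trna_rows):
        items.append(
            ("tRNA", [(int(r["start"]), int(r["end"])) for _, r in trna_rows.iterrows()])
        )
    for name, intervals in items:
        obs_mask = np.zeros(len(pos), dtype=bool)
        null_mask = np.zeros(draws.shape, dtype=bool)
        for s, e in intervals:
            obs_mask |= _region_membership(pos, s, e, mt_length)
            null_mask |= _region_membership(draws, s, e, mt_length)
        results[name] = _permutation_p(
            name, int(obs_mask.sum()), null_mask.sum(axis=1), seed, len(pos)
        )
    return results


def breakpoint_window_correlation(
    numt_breakpoints: Sequence[int],
    deletion_breakpoints: Sequence[int],
    mt_length: int,
    window: int = 100,
) -> dict:
    """Pearson correlation of per-window breakpoint frequencies on mtDNA.

    Both 1-based breakpoint sets are binned into fixed windows (default
    100 bp — 166 windows on a 16,569 bp genome); returns r with a two-sided
    p, NA when either binned vector is all-zero or constant.
    """
    n_windows = int(np.ceil(mt_length / window))
    edges = np.arange(0, (n_windows + 1) * window, window)

    def binned(points: Sequence[int]) -> np.ndarray:
        arr = np.asarray(list(points), dtype=np.int64) - 1
        counts, _ = np.histogram(arr, bins=edges)
        return counts.astype(float)

    x, y = binned(numt_breakpoints), binned(deletion_breakpoints)
    if x.sum() == 0 or y.sum() == 0 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n_windows": n_windows}
    x /= x.sum()
    y /= y.sum()
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n_windows": n_windows}


def distance_to_nearest_feature(
    numt_positions: Sequence[tuple[str, int]],
    track: IntervalTrack,
    reference: Optional[ReferenceGenome] = None,
    thresholds: tuple[int, ...] = (1000, 3000),
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Distance from each nuclear breakpoint to the nearest track feature.

    Distance 0 inside a feature; chromosomes without features yield an
    infinite sentinel, excluded from threshold summaries (count reported).
    With ``n_permutations`` > 0, an enrichment p for each "within d"
    indicator is computed by the count-and-chromosome matched null.
    """
    distances = []
    no_feature = 0
    for contig, pos in numt_positions:
        ivs = track.by_contig(contig)
        if not ivs:
            distances.append(float("inf"))
            no_feature += 1
            continue
        p0 = pos - 1
        best = min(
            0 if iv[1] <= p0 < iv[2] else min(abs(iv[1] - p0), abs(p0 - (iv[2] - 1)))
            for iv in ivs
        )
        distances.append(float(best))
    arr = np.asarray(distances)
    finite = arr[np.isfinite(arr)]
    out = {
        "distances": distances,
        "n": len(distances),
        "n_no_feature": no_feature,
        "within": {d: int((finite <= d).sum()) for d in thresholds},
    }
    if n_permutations and reference is not None:
        for d in thresholds:
            widened = IntervalTrack(
                name=f"{track.name}±{d}",
                intervals=[
                    (iv[0], max(0, iv[1] - d), iv[2] + d) for iv in track.intervals
                ],
            )
            out[f"permutation_within_{d}"] = permutation_enrichment(
                numt_positions, widened, reference,
                n_permutations=n_permutations, seed=seed, flank=0,
            )
    return out


MODEL_COVARIATES = [
    "Lchr", "Pcentro", "Pcpg", "Pline", "Pltr", "Pretroposon",
    "Psine", "Pmicrosat", "Prmsk", "Prepeats", "Pdups", "Preg",
]


def chromosome_count_model(
    data: pd.DataFrame, covariates: Optional[list[str]] = None
) -> pd.DataFrame:
    """OLS of per-chromosome NUMT counts on chromosome length and the
    log2-transformed genomic-feature proportions.

    Returns the coefficient table (estimate, std err, t, two-sided p); the
    Lchr row carries the headline length association. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    covariates = covariates or [c for c in MODEL_COVARIATES if c in data.columns]
    if "Nnumt" not in data.columns:
        raise ConfigurationError("data must contain an Nnumt column")
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ConfigurationError(f"missing covariates: {missing}")
    if len(data) < len(covariates) + 2:
        raise ConfigurationError(
            f"need >= {len(covariates) + 2} rows for {len(covariates)} covariates"
        )
    X = sm.add_constant(data[covariates].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name offending columns via QR: tiny diagonal entries mark dependence
        _, R = np.linalg.qr(X.values)
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ConfigurationError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(data["Nnumt"].astype(float), X).fit()
    return pd.DataFrame(
        {
            "estimate": model.params,
            "std_err": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
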