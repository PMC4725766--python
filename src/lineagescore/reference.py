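"""Reference-panel preprocessing: from raw log intensities to weight profiles.

A reference panel of haematopoietic expression profiles (genes x replicate
arrays) is turned into one pair of gene-weight vectors per lineage:

1. median-normalize each gene across cell types (subtract the per-gene
   median of the log intensities), giving relative expression;
2. z-transform each column to a standard-normal profile;
3. collapse replicates of a lineage by averaging z-scores, then
   re-z-transform each collapsed column;
4. split each z-profile into an upregulated part (z > 0) and a
   downregulated part (z < 0);
5. convert z-scores to one-sided tail probabilities, take -log10, trim at
   ``trim`` (default 10) and rescale by the global maximum so weights lie
   in [0, 1].

The resulting up/down weight pair is the input to the scoring stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TRIM = 10.0

#: Control or ambiguously named cell types removed from the murine panel.
DEFAULT_LINEAGE_EXCLUSIONS = (
    "CD4posTESTNA",
    "CD4posTESTDB",
    "CD4TESTJS",
    "CD4TESTCJ",
    "CD19CONTROL",
    "CD4CONTROL",
    "AG",
)


@dataclass
class ReferencePanel:
    """A reference expression panel plus its replicate and lineage metadata.

    Attributes
    ----------
    expression : DataFrame
        genes x replicate arrays, log-scale intensities.
    replicate_map : dict
        replicate column id -> lineage id; must cover every column.
    lineage_meta : DataFrame or None
        indexed by lineage; columns ``group`` (dedifferentiated / innate /
        adaptive / stromal / none) and ``subtype``.
    """

    expression: pd.DataFrame
    replicate_map: dict[str, str]
    lineage_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.expression.columns if c not in self.replicate_map]
        if missing:
            raise ValueError(f"replicate map does not cover columns: {missing[:5]}")
        if not set(self.replicate_map.values()):
            raise ValueError("replicate map names no lineages")

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.expression.columns:
            seen.setdefault(self.replicate_map[col], None)
        return list(seen)


@dataclass
class WeightProfilePair:
    """Per-lineage up/down gene-weight matrices in [0, 1].

    ``up`` and ``down`` are genes x lineages; for every (gene, lineage) at
    most one of the two is non-zero. Down-weights are stored as
    non-negative magnitudes; direction is carried by the matrix they live
    in. ``rescale_denominator`` is the global pre-rescale maximum.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    rescale_denominator: float = 1.0
    trim: float = DEFAULT_TRIM
    #: False only for the literal split-weight variant, where discordant
    #: genes carry -log10(0.5) mass in both profiles.
    mutually_exclusive: bool = True

    def __post_init__(self) -> None:
        if not self.up.index.equals(self.down.index) or not self.up.columns.equals(
            self.down.columns
        ):
            raise ValueError("up/down matrices must share genes and lineages")
        for name, m in (("up", self.up), ("down", self.down)):
            v = m.to_numpy()
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{name} weights outside [0, 1]")
        if self.mutually_exclusive and (
            self.up.to_numpy() * self.down.to_numpy() != 0
        ).any():
            raise ValueError("up and down weights are not mutually exclusive")

    @property
    def genes(self) -> pd.Index:
        return self.up.index

    @property
    def lineages(self) -> pd.Index:
        return self.up.columns

    def to_long(self) -> pd.DataFrame:
        """Long-format (gene, lineage, direction, weight) with zeros dropped."""
        frames = []
        for direction, m in (("up", self.up), ("down", self.down)):
            long = m.stack().rename("weight").reset_index()
            long.columns = ["gene", "lineage", "weight"]
            long["direction"] = direction
            frames.append(long[long["weight"] > 0])
        return pd.concat(frames, ignore_index=True)[
            ["gene", "lineage", "direction", "weight"]
        ]

    @classmethod
    def from_long(cls, long: pd.DataFrame, trim: float = DEFAULT_TRIM) -> "WeightProfilePair":
        genes = pd.Index(sorted(long["gene"].unique()), name="gene")
        lineages = pd.Index(long["lineage"].unique(), name="lineage")
        mats = {}
        for direction in ("up", "down"):
            sub = long[long["direction"] == direction]
            m = sub.pivot(index="gene", columns="lineage", values="weight")
            mats[direction] = m.reindex(index=genes, columns=lineages).fillna(0.0)
        return cls(up=mats["up"], down=mats["down"], trim=trim)


def median_normalize_across_columns(expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across columns (log-scale subtraction)."""
    if expr.shape[1] < 2:
        raise ValueError("median normalization needs at least 2 columns")
    return expr.sub(expr.median(axis=1), axis=0)


def ztransform_columns(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sd 1 (population sd, divide by n)."""
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd
    zero = sd == 0
    if zero.any():
        bad = list(expr.columns[zero])
        raise ValueError(f"zero-variance column(s): {bad}")
    return pd.DataFrame((values - mean) / sd, index=expr.index, columns=expr.columns)


def collapse_replicates(z: pd.DataFrame, replicate_map: dict[str, str]) -> pd.DataFrame:
    """Average replicate z-columns per lineage, then re-z-transform.

    Column order of the result follows first appearance of each lineage.
    """
    missing = [c for c in z.columns if c not in replicate_map]
    if missing:
        raise ValueError(f"replicate map does not cover columns: {missing[:5]}")
    order: dict[str, list[str]] = {}
    for col in z.columns:
        order.setdefault(replicate_map[col], []).append(col)
    collapsed = pd.DataFrame(
        {lin: z[cols].mean(axis=1) for lin, cols in order.items()}, index=z.index
    )
    collapsed.columns.name = "lineage"
    return ztransform_columns(collapsed)


def split_up_down(z: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a z-profile matrix into up (z > 0) and down (z < 0) parts.

    Entries outside each part are zeroed; ``up + down == z`` element-wise.
    """
    up = z.where(z > 0, 0.0)
    down = z.where(z < 0, 0.0)
    return up, down


def z_to_weights(
    up_z: pd.DataFrame, down_z: pd.DataFrame, trim: float = DEFAULT_TRIM,
    literal_split_weights: bool = False,
) -> WeightProfilePair:
    """Convert split z-profiles to [0, 1] weight matrices.

    Non-zero up entries map through the upper-tail standard-normal
    probability, non-zero down entries through the lower tail; both are
    -log10 transformed, trimmed at ``trim``, and divided by the single
    global maximum over both matrices.

    Entries zeroed by the split stay exactly 0 by default, so discordant
    genes carry no foreground mass. ``literal_split_weights=True`` instead
    assigns them -log10(0.5), the value a literal tail-probability reading
    would give.
    """
    if trim <= 0:
        raise ValueError("trim must be positive")

    def _transform(z: pd.DataFrame, upper: bool) -> np.ndarray:
        zv = z.to_numpy(dtype=float)
        active = zv > 0 if upper else zv < 0
        p = stats.norm.sf(zv) if upper else stats.norm.cdf(zv)
        with np.errstate(divide="ignore"):
            w = np.minimum(-np.log10(p), trim)
        if literal_split_weights:
            return np.where(active, w, -np.log10(0.5))
        return np.where(active, w, 0.0)

    up_w = _transform(up_z, upper=True)
    down_w = _transform(down_z, upper=False)
    denom = max(up_w.max(initial=0.0), down_w.max(initial=0.0))
    if denom <= 0:
        raise ValueError("degenerate reference: all weights are zero")
    return WeightProfilePair(
        up=pd.DataFrame(up_w / denom, index=up_z.index, columns=up_z.columns),
        down=pd.DataFrame(down_w / denom, index=down_z.index, columns=down_z.columns),
        rescale_denominator=float(denom),
        trim=trim,
        mutually_exclusive=not literal_split_weights,
    )


def build_weight_profiles(
    panel: ReferencePanel, trim: float = DEFAULT_TRIM,
    literal_split_weights: bool = False,
) -> WeightProfilePair:
    """Run the full preprocessing pipeline on a reference panel.

    median-normalize -> z-transform -> collapse replicates -> split ->
    weight transform. Deterministic: no randomness is involved.
    """
    rel = median_normalize_across_columns(panel.expression)
    z = ztransform_columns(rel)
    collapsed = collapse_replicates(z, panel.replicate_map)
    up_z, down_z = split_up_down(collapsed)
    return z_to_weights(up_z, down_z, trim=trim,
                        literal_split_weights=literal_split_weights)


def extract_minimal_gene_sets(weights: WeightProfilePair) -> pd.DataFrame:
    """Restrict the up-weight matrix to genes with weight exactly 1 somewhere.

    A weight of 1 marks the strongest differential expression after
    trimming and rescaling; the reduced matrix is the "minimal gene set"
    representation of the panel. Logs the per-lineage count of weight-1
    genes. Returns an empty frame (with a warning) if no gene qualifies.
    """
    hit = (weights.up == 1.0).any(axis=1)
    reduced = weights.up.loc[hit]
    if reduced.empty:
        logger.warning("extract_minimal_gene_sets: no gene reaches weight 1.0")
        return reduced
    counts = (reduced == 1.0).sum(axis=0)
    for lineage, n in counts.items():
        logger.info("minimal gene set: lineage %s has %d weight-1 genes", lineage, n)
    return reduced


def shuffle_reference(expr: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute each gene's values independently across columns.

    Produces novel, biologically meaningless cell profiles with each
    gene's value multiset preserved; used as a sensitivity control.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 columns to shuffle")
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float).copy()
    n_rows, n_cols = values.shape
    # independent row-wise permutations via argsort of uniform draws
    perm = np.argsort(rng.random((n_rows, n_cols)), axis=1)
    shuffled = np.take_along_axis(values, perm, axis=1)
    return pd.DataFrame(shuffled, index=expr.index, columns=expr.columns)


def filter_lineages(
    lineages: list[str], exclusion: tuple[str, ...] | list[str] = DEFAULT_LINEAGE_EXCLUSIONS
) -> list[str]:
    """Drop excluded lineage names (exact match), preserving order.

    Exclusion names absent from the input are logged, not errors.
    """
    excl = set(exclusion)
    absent = excl - set(lineages)
    if absent:
        logger.warning("filter_lineages: exclusion names not present: %s", sorted(absent))
    return [lin for lin in lineages if lin not in excl]
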