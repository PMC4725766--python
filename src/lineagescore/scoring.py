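"""The BASE rank-similarity statistic and the cell lineage score (CLS).

One tumour sample is summarized as a ranked relative-expression vector
``g`` (median-normalized log expression, sorted high to low). One lineage
is summarized as a gene-weight vector ``w`` in [0, 1]. Two cumulative
curves are walked down the ranking:

    foreground  f_i = sum_{j<=i} w_j |g_j| / sum_j w_j |g_j|
    background  b_i = sum_{j<=i} (1-w_j) |g_j| / sum_j (1-w_j) |g_j|

The pre-normalization score (pCLS) is the signed extreme deviation
between the two curves: the largest positive excursion (pCLS+) if it
beats the deepest negative one (pCLS-) in magnitude, the negative one
otherwise. Because f and b are both CDFs, |pCLS| <= 1.

Raw pCLS values are not comparable across lineages with different weight
sparsity, so each is normalized against a permutation null: gene labels
of g are permuted (equivalently, the weight vector is permuted against
the fixed ranked masses), the pCLS recomputed per permutation, and the
observed value divided by the mean absolute permuted pCLS. The final CLS
for a lineage is the normalized up-profile score minus the normalized
down-profile score.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import harmonize_symbols
from .reference import WeightProfilePair

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
_PERM_CHUNK = 256  # permutations processed per vectorized block
# excursions below this are accumulated rounding residue of the two unit
# CDFs (f, b in [0,1]); a mathematically zero deviation reports exactly 0
_ZERO_TOL = 1e-14


@dataclass
class RelativeExpressionVector:
    """One sample's ranked relative expression.

    ``genes`` and ``values`` are aligned and sorted by value descending;
    ties are broken by gene symbol so the ranking is deterministic.
    """

    genes: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.genes.shape != self.values.shape:
            raise ValueError("genes and values must align")
        if np.any(np.diff(self.values) > 0):
            raise ValueError("values must be sorted non-increasing")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_unsorted(
        cls, genes: np.ndarray, values: np.ndarray, sample_id: str = ""
    ) -> "RelativeExpressionVector":
        genes = np.asarray(genes, dtype=object)
        values = np.asarray(values, dtype=float)
        # stable sort on gene symbol first, then descending value
        order = np.argsort(genes, kind="stable")
        order = order[np.argsort(-values[order], kind="stable")]
        return cls(genes=genes[order], values=values[order], sample_id=sample_id)


@dataclass
class DeviationCurves:
    """Foreground/background cumulative curves over the ranking."""

    f: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.f.shape != self.b.shape:
            raise ValueError("curves must align")


@dataclass
class PCLSResult:
    """Signed extreme deviation between foreground and background curves."""

    pcls_plus: float
    pcls_minus: float
    pcls: float
    direction: str  # "up" if the positive excursion was selected


def _masses(g: RelativeExpressionVector, mass: str) -> np.ndarray:
    if mass == "abs":
        return np.abs(g.values)
    if mass == "rank":
        return np.ones(g.n)
    raise ValueError(f"unknown mass scheme {mass!r}")


def normalize_patient_expression(expr: pd.DataFrame) -> list[RelativeExpressionVector]:
    """Median-normalize log expression across samples; rank each sample.

    Subtracts each gene's median across samples (so per-gene medians of
    the output are 0), then sorts each sample's genes by the resulting
    relative value, high to low. Requires >= 2 samples, otherwise the
    cross-sample median is meaningless.
    """
    if expr.shape[1] < 2:
        raise ValueError(
            "patient median normalization needs >= 2 samples "
            "(or an external median reference)"
        )
    rel = expr.sub(expr.median(axis=1), axis=0)
    genes = rel.index.to_numpy(dtype=object)
    out = []
    for sample in rel.columns:
        vec = RelativeExpressionVector.from_unsorted(
            genes, rel[sample].to_numpy(), sample_id=str(sample)
        )
        if np.allclose(vec.values, 0):
            logger.warning(
                "sample %s has all-zero relative expression; ranks are degenerate",
                sample,
            )
        out.append(vec)
    return out


def deviation_curves(
    g: RelativeExpressionVector, w: np.ndarray, mass: str = "abs"
) -> DeviationCurves:
    """Compute foreground/background cumulative curves for one profile.

    ``w`` must be aligned to ``g``'s gene order. The cumulative mass of
    each gene is ``|g_j|`` (``mass="abs"``, default) or 1 (``mass="rank"``).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != g.values.shape:
        raise ValueError("weight vector not aligned to expression vector")
    m = _masses(g, mass)
    fg = w * m
    bg = (1.0 - w) * m
    fg_total = fg.sum()
    bg_total = bg.sum()
    if fg_total <= 0 or bg_total <= 0:
        raise ValueError(
            "degenerate profile: foreground or background mass is zero"
        )
    return DeviationCurves(f=np.cumsum(fg) / fg_total, b=np.cumsum(bg) / bg_total)


def pcls(curves: DeviationCurves) -> PCLSResult:
    """Select the signed extreme deviation between the two curves.

    Ties in magnitude between the positive and negative excursions return
    the positive one (measure-zero event for real data).
    """
    d = curves.f - curves.b
    plus = max(float(d.max()), 0.0)
    minus = min(float(d.min()), 0.0)
    if plus < _ZERO_TOL:
        plus = 0.0
    if minus > -_ZERO_TOL:
        minus = 0.0
    if plus >= -minus:
        return PCLSResult(plus, minus, plus, "up")
    return PCLSResult(plus, minus, minus, "down")


def _pcls_values(masses: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized pCLS for one or many weight rows against fixed masses.

    ``weights`` has shape (k, n); returns k signed pCLS values. Rows with
    zero foreground or background mass yield NaN.
    """
    fg = weights * masses
    bg = (1.0 - weights) * masses
    fg_tot = fg.sum(axis=1, keepdims=True)
    bg_tot = bg.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.cumsum(fg, axis=1) / fg_tot - np.cumsum(bg, axis=1) / bg_tot
    plus = np.maximum(d.max(axis=1), 0.0)
    minus = np.minimum(d.min(axis=1), 0.0)
    out = np.where(plus >= -minus, plus, minus)
    bad = (fg_tot[:, 0] <= 0) | (bg_tot[:, 0] <= 0)
    out = np.where(bad, np.nan, out)
    return out


def _null_mean_abs(
    masses: np.ndarray, w: np.ndarray, perms: np.ndarray
) -> float:
    """Mean |pCLS| over permutations of the gene labels.

    ``perms`` is an (n_perm, n) index matrix; each row realigns the weight
    vector against the fixed ranked masses.
    """
    total = 0.0
    n_perm = perms.shape[0]
    for start in range(0, n_perm, _PERM_CHUNK):
        chunk = perms[start : start + _PERM_CHUNK]
        vals = _pcls_values(masses, w[chunk])
        total += np.abs(vals).sum()
    return total / n_perm


def _make_perms(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def normalize_pcls(
    observed: PCLSResult,
    g: RelativeExpressionVector,
    w: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    mass: str = "abs",
    rng: np.random.Generator | None = None,
    perms: np.ndarray | None = None,
) -> float:
    """Normalize an observed pCLS by its gene-label permutation null.

    Returns ``observed.pcls / mean(|permuted pCLS|)``. The permutation
    stream is reproducible from ``seed``; a precomputed permutation index
    matrix may be supplied to share the null across profiles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    w = np.asarray(w, dtype=float)
    m = _masses(g, mass)
    if perms is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        perms = _make_perms(rng, g.n, n_perm)
    null_mean = _null_mean_abs(m, w, perms)
    if null_mean < 1e-12:
        raise ValueError("permutation null has zero mean |pCLS|; score undefined")
    return observed.pcls / null_mean


def compute_cls(
    g: RelativeExpressionVector,
    up_w: np.ndarray,
    down_w: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    mass: str = "abs",
    perms: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """CLS for one sample against one lineage: ``CLS_up - CLS_dn``.

    Returns (cls, cls_up, cls_dn). An all-zero down profile contributes 0
    (logged); likewise for up.
    """
    if perms is None:
        rng = np.random.default_rng(seed)
        perms = _make_perms(rng, g.n, n_perm)

    def _one(w: np.ndarray, label: str) -> float:
        if not np.any(w > 0):
            logger.info("all-zero %s profile; contributes 0 to the CLS", label)
            return 0.0
        observed = pcls(deviation_curves(g, w, mass=mass))
        return normalize_pcls(observed, g, w, n_perm=n_perm, mass=mass, perms=perms)

    cls_up = _one(np.asarray(up_w, float), "up")
    cls_dn = _one(np.asarray(down_w, float), "down")
    return cls_up - cls_dn, cls_up, cls_dn


@dataclass
class CLSMatrix:
    """Samples x lineages matrix of cell lineage scores with provenance."""

    scores: pd.DataFrame
    n_perm: int
    seed: int
    cls_up: pd.DataFrame | None = None
    cls_dn: pd.DataFrame | None = None
    reference_hash: str = ""
    missing: list[tuple[str, str, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# n_perm={self.n_perm}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write(f"# reference_hash={self.reference_hash}\n")
            self.scores.to_csv(fh, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CLSMatrix":
        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            scores = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(
            scores=scores,
            n_perm=int(meta.get("n_perm", 0)),
            seed=int(meta.get("seed", 0)),
            reference_hash=meta.get("reference_hash", ""),
        )


def _profile_hash(profiles: WeightProfilePair) -> str:
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(profiles.up.to_numpy()).tobytes())
    digest.update(np.ascontiguousarray(profiles.down.to_numpy()).tobytes())
    digest.update(",".join(map(str, profiles.lineages)).encode())
    return digest.hexdigest()[:16]


def compute_cls_matrix(
    patients: pd.DataFrame,
    profiles: WeightProfilePair,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    mass: str = "abs",
    shared_permutations: bool = True,
    keep_updn: bool = False,
    match_floor: float = 0.5,
) -> CLSMatrix:
    """Score every sample against every lineage.

    Gene spaces are harmonized case-insensitively and scoring restricted
    to the intersection. One permutation stream per sample is reused
    across lineages and both directions by default (valid because the
    null permutes the sample vector, which is lineage-independent);
    ``shared_permutations=False`` draws an independent null per
    (sample, lineage, direction) cell. A failed cell is recorded in
    ``missing`` with its reason and the run continues.
    """
    pairs = harmonize_symbols(
        list(profiles.genes), list(patients.index), match_floor=match_floor
    )
    ref_genes = [r for r, _ in pairs]
    pat_genes = [p for _, p in pairs]
    up = profiles.up.loc[ref_genes]
    down = profiles.down.loc[ref_genes]
    expr = patients.loc[pat_genes]
    # score in the reference symbol space
    expr = expr.set_axis(ref_genes, axis=0)

    vectors = normalize_patient_expression(expr)
    lineages = list(profiles.lineages)
    samples = [v.sample_id for v in vectors]
    n_genes = len(ref_genes)

    scores = np.full((len(samples), len(lineages)), np.nan)
    up_scores = np.full_like(scores, np.nan)
    dn_scores = np.full_like(scores, np.nan)
    missing: list[tuple[str, str, str]] = []

    rng = np.random.default_rng(seed)
    gene_pos = pd.Index(ref_genes)
    up_arr = up.to_numpy()
    down_arr = down.to_numpy()

    for i, vec in enumerate(vectors):
        # weights aligned to this sample's ranking
        order = gene_pos.get_indexer(vec.genes)
        perms = _make_perms(rng, n_genes, n_perm) if shared_permutations else None
        for k, lineage in enumerate(lineages):
            try:
                cell_perms = (
                    perms
                    if shared_permutations
                    else _make_perms(rng, n_genes, n_perm)
                )
                cls, cls_up, cls_dn = compute_cls(
                    vec,
                    up_arr[order, k],
                    down_arr[order, k],
                    n_perm=n_perm,
                    mass=mass,
                    perms=cell_perms,
                )
                scores[i, k] = cls
                up_scores[i, k] = cls_up
                dn_scores[i, k] = cls_dn
            except ValueError as exc:
                missing.append((vec.sample_id, lineage, str(exc)))
                logger.warning(
                    "CLS failed for sample %s, lineage %s: %s",
                    vec.sample_id, lineage, exc,
                )

    def _frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=pd.Index(samples, name="sample"),
                            columns=pd.Index(lineages, name="lineage"))

    return CLSMatrix(
        scores=_frame(scores),
        n_perm=n_perm,
        seed=seed,
        cls_up=_frame(up_scores) if keep_updn else None,
        cls_dn=_frame(dn_scores) if keep_updn else None,
        reference_hash=_profile_hash(profiles),
        missing=missing,
    )
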