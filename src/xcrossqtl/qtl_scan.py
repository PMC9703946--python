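"""Single-QTL genome scans for a backcross.

Two scan statistics are provided, both evaluated on the conditional
genotype probabilities of :mod:`xcrossqtl.genoprob`:

* ``em_scan`` -- interval mapping by maximum likelihood.  At each position
  the trait is modelled as a two-component normal mixture with known,
  individual-specific mixing weights ``p_ig`` (the genotype probabilities)
  and a common residual SD.  The mixture is fitted by EM (E-step
  ``w_ig \\propto p_ig phi(y_i; mu_g, sigma)``; M-step weighted means and
  pooled variance), initialised from the single-pass regression of the
  trait on P(H).  LOD = log10 of the mixture likelihood over the
  single-normal null likelihood.

* ``np_scan`` -- a nonparametric (rank-based) scan: the extension of the
  Kruskal-Wallis statistic to probabilistic genotype weights, with the
  usual tie correction, reported on the LOD scale (H / (2 ln 10)).  At a
  fully informative marker it reduces exactly to Kruskal-Wallis on the two
  genotype groups.

Genome-wide significance thresholds come from permutation of the phenotype
vector against the fixed genotypes; support intervals are 95% Bayes
credible intervals (default) or 1.5-LOD drop intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GENOTYPE_A, GENOTYPE_H, CrossPopulation, ValidationError
from .genoprob import GenotypeProbabilities

LN10 = math.log(10.0)


class DegeneratePhenotypeError(ValueError):
    """Raised when a trait has fewer than two distinct non-missing values."""


# ---------------------------------------------------------------------------
# trait preprocessing
# ---------------------------------------------------------------------------

def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K^2, p).

    K^2 is the sum of the squared normalizing transforms of sample skewness
    and kurtosis, referred to chi-square with 2 df.  Requires n >= 20 for
    the kurtosis approximation to be valid.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 20:
        raise ValueError(f"normality test needs n >= 20 (got n={len(x)})")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def log2_transform(values):
    """Elementwise log2; missing values preserved, nonpositive values rejected."""
    s = pd.Series(values, dtype=float)
    bad = s.index[(s <= 0).fillna(False)]
    if len(bad):
        raise ValueError(
            f"log2 transform needs positive values; individual {bad[0]!r} "
            f"has value {s[bad[0]]!r}"
        )
    out = np.log2(s)
    return out if isinstance(values, pd.Series) else out.to_numpy()


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """LOD curve for one trait on the evaluation grid of a probability set."""

    trait: str
    method: str  # "em" | "np"
    positions: pd.DataFrame  # chrom, cm, is_marker, name, nearest_marker
    lod: np.ndarray
    n: int
    transform: str | None = None

    def chrom_slice(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(self.positions["chrom"].to_numpy() == str(chrom))
        return self.positions["cm"].to_numpy()[idx], self.lod[idx]

    def max_lod(self, chrom: str | None = None) -> float:
        if chrom is None:
            return float(self.lod.max())
        return float(self.chrom_slice(chrom)[1].max())

    def peak(self, chrom: str | None = None) -> tuple[str, float, float]:
        """(chrom, cm, lod) at the global (or per-chromosome) max; ties -> leftmost."""
        if chrom is None:
            i = int(np.argmax(self.lod))
            row = self.positions.iloc[i]
            return str(row["chrom"]), float(row["cm"]), float(self.lod[i])
        cm, lod = self.chrom_slice(chrom)
        i = int(np.argmax(lod))
        return str(chrom), float(cm[i]), float(lod[i])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.positions["chrom"]))

    def to_tsv(self, path) -> None:
        df = self.positions[["chrom", "cm"]].copy()
        df["lod"] = self.lod
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PermutationResult:
    """Genome-wide max LODs under phenotype permutation."""

    trait: str
    maxima: np.ndarray
    seed: int
    method: str

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=float)

    @property
    def n_perm(self) -> int:
        return len(self.maxima)

    def threshold(self, alpha: float = 0.05) -> float:
        """Empirical (1 - alpha) quantile, linear interpolation between
        order statistics."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return float(np.quantile(self.maxima, 1.0 - alpha, method="linear"))


@dataclass
class ClassStats:
    mean: float
    sem: float
    n: int


@dataclass
class QtlSummary:
    """One significant QTL: peak, support interval, closest marker, effects."""

    trait: str
    chromosome: str
    peak_cm: float
    max_lod: float
    ci_lo: float
    ci_hi: float
    closest_marker: str
    closest_marker_mbp: float
    class_stats: dict[str, ClassStats]
    cross_label: str = ""
    weeks: list | None = None
    ci_method: str = "bayes"

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.peak_cm <= self.ci_hi):
            raise ValidationError("support interval does not contain the peak")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.ci_lo, self.ci_hi)

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait,
            "chromosome": self.chromosome,
            "peak_cm": self.peak_cm,
            "max_lod": self.max_lod,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "ci_method": self.ci_method,
            "closest_marker": self.closest_marker,
            "closest_marker_mbp": self.closest_marker_mbp,
            "cross": self.cross_label,
            "weeks": self.weeks,
            "classes": {
                k: {"mean": v.mean, "sem": v.sem, "n": v.n}
                for k, v in self.class_stats.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QtlSummary":
        return cls(
            trait=d["trait"],
            chromosome=str(d["chromosome"]),
            peak_cm=float(d["peak_cm"]),
            max_lod=float(d["max_lod"]),
            ci_lo=float(d["ci_lo"]),
            ci_hi=float(d["ci_hi"]),
            closest_marker=d["closest_marker"],
            closest_marker_mbp=float(d["closest_marker_mbp"]),
            class_stats={
                k: ClassStats(v["mean"], v["sem"], v["n"])
                for k, v in d.get("classes", {}).items()
            },
            cross_label=d.get("cross", ""),
            weeks=d.get("weeks"),
            ci_method=d.get("ci_method", "bayes"),
        )


# ---------------------------------------------------------------------------
# trait alignment helpers
# ---------------------------------------------------------------------------

def _aligned_trait(probs: GenotypeProbabilities, y) -> np.ndarray:
    if isinstance(y, pd.Series):
        y = y.reindex(probs.individuals)
    y = np.asarray(y, dtype=float)
    if len(y) != len(probs.individuals):
        raise ValidationError(
            f"trait length {len(y)} does not match {len(probs.individuals)} individuals"
        )
    return y


def _complete_cases(probs: GenotypeProbabilities, y) -> tuple[np.ndarray, np.ndarray]:
    """Drop individuals with missing trait; return (p, y) with p (P, n, 2)."""
    yv = _aligned_trait(probs, y)
    mask = np.isfinite(yv)
    yv = yv[mask]
    if len(np.unique(yv)) < 2:
        raise DegeneratePhenotypeError(
            "degenerate phenotype: fewer than two distinct non-missing values"
        )
    p = probs.probs[mask].transpose(1, 0, 2)
    return p, yv


# ---------------------------------------------------------------------------
# EM interval mapping
# ---------------------------------------------------------------------------

EM_TOL = 1e-6
EM_MAX_ITER = 1000
_TARGET_CHUNK_ELEMENTS = 4_000_000  # keeps per-chunk arrays ~tens of MB


def _em_lod_profile(
    p: np.ndarray,
    Y: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    track: list | None = None,
) -> np.ndarray:
    """LOD profiles for several traits at once.

    p: (P, n, 2) genotype probabilities; Y: (T, n) complete traits.
    Returns (T, P) LODs.  ``track`` (testing hook) collects the per-iteration
    mixture log-likelihood arrays of each chunk.
    """
    P, n, _ = p.shape
    T = Y.shape[0]
    s0 = Y.var(axis=1)
    if np.any(s0 <= 0):
        raise DegeneratePhenotypeError("degenerate phenotype: zero variance")
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * s0) + 1.0)

    lods = np.empty((T, P))
    chunk = max(1, int(_TARGET_CHUNK_ELEMENTS // max(1, P * n * 2)))
    for t0 in range(0, T, chunk):
        sl = slice(t0, min(t0 + chunk, T))
        lods[sl] = _em_chunk(p, Y[sl], ll0[sl], tol, max_iter, track)
    return np.maximum(lods, 0.0)


def _em_chunk(p, Yc, ll0c, tol, max_iter, track):
    t, n = Yc.shape
    y = Yc[:, None, :, None]  # (t, 1, n, 1)
    logp = np.log(np.maximum(p, 1e-300))[None]  # (1, P, n, 2)

    # initialisation: single-pass regression of y on P(H) at each position
    x = p[:, :, 1]  # (P, n)
    xm = x.mean(axis=1)
    xc = x - xm[:, None]
    sxx = np.maximum((xc**2).sum(axis=1), 1e-12)
    ym = Yc.mean(axis=1)
    sxy = xc @ Yc.T  # (P, t)
    b = (sxy / sxx[:, None]).T  # (t, P)
    a = ym[:, None] - b * xm[None, :]
    syy = ((Yc - ym[:, None]) ** 2).sum(axis=1)
    sig2 = np.maximum((syy[:, None] - b * sxy.T) / n, 1e-12)

    mu = np.stack([a, a + b], axis=-1)[:, :, None, :]  # (t, P, 1, 2)
    s2 = sig2[:, :, None, None]

    ll_prev = None
    ll = None
    for _ in range(max_iter):
        logphi = -0.5 * (np.log(2.0 * np.pi * s2) + (y - mu) ** 2 / s2)
        lj = logp + logphi  # (t, P, n, 2)
        m = lj.max(axis=-1, keepdims=True)
        e = np.exp(lj - m)
        se = e.sum(axis=-1)  # (t, P, n)
        ll = (m[..., 0] + np.log(se)).sum(axis=-1)  # (t, P)
        if track is not None:
            track.append(ll.copy())
        if ll_prev is not None:
            if np.any(ll < ll_prev - 1e-6):
                raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
            if np.abs(ll - ll_prev).max() < tol:
                break
        ll_prev = ll
        w = e / se[..., None]  # (t, P, n, 2)
        sw = np.maximum(w.sum(axis=2), 1e-12)  # (t, P, 2)
        mu = ((w * y).sum(axis=2) / sw)[:, :, None, :]
        s2 = np.maximum((w * (y - mu) ** 2).sum(axis=(2, 3)) / n, 1e-12)[
            :, :, None, None
        ]
    return (ll - ll0c[:, None]) / LN10


def em_scan(
    probs: GenotypeProbabilities,
    y,
    trait: str = "trait",
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    transform: str | None = None,
) -> ScanResult:
    """EM interval-mapping scan of one trait; missing trait values dropped."""
    p, yv = _complete_cases(probs, y)
    lod = _em_lod_profile(p, yv[None, :], tol=tol, max_iter=max_iter)[0]
    return ScanResult(trait, "em", probs.positions.copy(), lod, len(yv), transform)


# ---------------------------------------------------------------------------
# nonparametric (rank) scan
# ---------------------------------------------------------------------------

def _tie_correction(Y: np.ndarray) -> np.ndarray:
    """1 - sum(t^3 - t)/(n^3 - n) per trait row."""
    T, n = Y.shape
    corr = np.ones(T)
    for i in range(T):
        _, counts = np.unique(Y[i], return_counts=True)
        corr[i] = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return corr


def _np_lod_profile(p: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Rank-based LOD profiles; p: (P, n, 2), Y: (T, n) -> (T, P)."""
    T, n = Y.shape
    R = stats.rankdata(Y, axis=1)  # mid-ranks
    S = np.einsum("tn,png->tpg", R, p)
    D = np.maximum(p.sum(axis=1), 1e-12)  # (P, 2)
    H = 12.0 / (n * (n + 1)) * (S**2 / D[None]).sum(axis=-1) - 3.0 * (n + 1)
    corr = _tie_correction(Y)
    if np.any(corr <= 0):
        raise DegeneratePhenotypeError("degenerate phenotype: all values tied")
    H = H / corr[:, None]
    return np.maximum(H, 0.0) / (2.0 * LN10)


def np_scan(probs: GenotypeProbabilities, y, trait: str = "trait") -> ScanResult:
    """Nonparametric rank scan (probability-weighted Kruskal-Wallis on the
    LOD scale); invariant under strictly monotone trait transforms."""
    p, yv = _complete_cases(probs, y)
    lod = _np_lod_profile(p, yv[None, :])[0]
    return ScanResult(trait, "np", probs.positions.copy(), lod, len(yv))


_SCANNERS = {"em": _em_lod_profile, "np": _np_lod_profile}


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

def permutation_threshold(
    probs: GenotypeProbabilities,
    y,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "em",
    trait: str = "trait",
) -> PermutationResult:
    """Genome-wide max-LOD null distribution by permuting the phenotype
    vector against the fixed genotype probabilities."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if method not in _SCANNERS:
        raise ValueError(f"unknown scan method {method!r}")
    p, yv = _complete_cases(probs, y)
    rng = np.random.default_rng(seed)
    n = len(yv)
    Y = np.empty((n_perm, n))
    for i in range(n_perm):
        Y[i] = yv[rng.permutation(n)]
    lods = _SCANNERS[method](p, Y)
    return PermutationResult(trait, lods.max(axis=1), seed, method)


# ---------------------------------------------------------------------------
# support intervals
# ---------------------------------------------------------------------------

def support_interval(
    scan: ScanResult,
    chrom: str,
    method: str = "bayes",
    coverage: float = 0.95,
    lod_drop: float = 1.5,
) -> tuple[float, float]:
    """Positional support interval on one chromosome.

    ``bayes``: smallest contiguous interval of evaluated positions holding
    >= ``coverage`` of the trapezoid-normalised mass of 10^LOD and containing
    the peak.  ``lod_drop``: outermost positions within ``lod_drop`` of the
    peak LOD.
    """
    cm, lod = scan.chrom_slice(chrom)
    if len(cm) == 0:
        raise ValidationError(f"chromosome {chrom!r} not in scan")
    if len(cm) == 1:
        return (float(cm[0]), float(cm[0]))
    if np.allclose(lod, 0.0):
        warnings.warn(
            f"flat LOD curve on chromosome {chrom}; interval spans the chromosome",
            stacklevel=2,
        )
        return (float(cm[0]), float(cm[-1]))

    if method == "lod_drop":
        keep = np.flatnonzero(lod >= lod.max() - lod_drop)
        return (float(cm[keep[0]]), float(cm[keep[-1]]))
    if method != "bayes":
        raise ValueError(f"unknown interval method {method!r}")

    # trapezoid weights: half the span between flanking neighbours
    width = np.empty_like(cm)
    width[1:-1] = (cm[2:] - cm[:-2]) / 2.0
    width[0] = (cm[1] - cm[0]) / 2.0
    width[-1] = (cm[-1] - cm[-2]) / 2.0
    mass = np.power(10.0, lod - lod.max()) * np.maximum(width, 1e-12)
    mass = mass / mass.sum()
    cmass = np.concatenate([[0.0], np.cumsum(mass)])
    peak = int(np.argmax(lod))

    best = (np.inf, 0, len(cm) - 1)
    for i in range(peak + 1):
        for j in range(peak, len(cm)):
            if cmass[j + 1] - cmass[i] >= coverage:
                length = cm[j] - cm[i]
                if length < best[0] - 1e-12:
                    best = (length, i, j)
                break
    return (float(cm[best[1]]), float(cm[best[2]]))


# ---------------------------------------------------------------------------
# peak summaries and genotype-class effects
# ---------------------------------------------------------------------------

def genotype_class_stats(
    cross: CrossPopulation, marker: str, trait: str
) -> dict[str, ClassStats]:
    """Mean, SEM and n of one trait per observed genotype class at a marker."""
    if marker not in cross.genotypes.columns:
        raise KeyError(f"unknown marker {marker!r}")
    g = cross.genotypes[marker]
    y = cross.phenotypes[trait]
    out: dict[str, ClassStats] = {}
    for cls in (GENOTYPE_A, GENOTYPE_H):
        vals = y[(g == cls) & y.notna()].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            out[cls] = ClassStats(math.nan, math.nan, 0)
        else:
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            out[cls] = ClassStats(float(vals.mean()), sem, n)
    return out


def _closest_marker(gmap, chrom: str, peak_cm: float) -> pd.Series:
    """Closest marker by |delta cM|; ties broken toward the smaller Mbp."""
    sub = gmap.markers_on(chrom)
    dist = np.abs(sub["cm"].to_numpy(dtype=float) - peak_cm)
    best = dist.min()
    cand = sub[np.isclose(dist, best)]
    if len(cand) > 1 and cand["mbp"].notna().all():
        cand = cand.sort_values("mbp", kind="stable")
    return cand.iloc[0]


def peak_summaries(
    scan: ScanResult,
    threshold: float,
    cross: CrossPopulation,
    trait: str | None = None,
    ci_method: str = "bayes",
    cross_label: str | None = None,
) -> list[QtlSummary]:
    """One QtlSummary per chromosome whose max LOD reaches the threshold."""
    trait = trait or scan.trait
    label = cross.cross_label if cross_label is None else cross_label
    out = []
    for chrom in scan.chromosomes():
        _, peak_cm, peak_lod = scan.peak(chrom)
        if peak_lod < threshold:
            continue
        lo, hi = support_interval(scan, chrom, method=ci_method)
        marker = _closest_marker(cross.gmap, chrom, peak_cm)
        stats_by_class = genotype_class_stats(cross, marker["marker"], trait)
        out.append(
            QtlSummary(
                trait=trait,
                chromosome=str(chrom),
                peak_cm=peak_cm,
                max_lod=peak_lod,
                ci_lo=lo,
                ci_hi=hi,
                closest_marker=str(marker["marker"]),
                closest_marker_mbp=float(marker["mbp"]),
                class_stats=stats_by_class,
                cross_label=label,
                ci_method=ci_method,
            )
        )
    return out


def summarize_longitudinal(
    scans: dict,
    thresholds: dict,
    cross: CrossPopulation,
    family: str,
    ci_method: str = "bayes",
) -> list[QtlSummary]:
    """Combine per-week scans of one trait family into per-chromosome
    summaries: the reported peak is from the week with the highest LOD
    (the week of maximal effect), and ``weeks`` lists every week whose own
    scan clears its own threshold on that chromosome."""
    chroms: list[str] = []
    for s in scans.values():
        for c in s.chromosomes():
            if c not in chroms:
                chroms.append(c)
    out = []
    for chrom in chroms:
        sig_weeks = [
            wk
            for wk, s in scans.items()
            if s.max_lod(chrom) >= thresholds[wk]
        ]
        if not sig_weeks:
            continue
        best_week = max(sig_weeks, key=lambda wk: scans[wk].max_lod(chrom))
        best = peak_summaries(
            scans[best_week],
            thresholds[best_week],
            cross,
            trait=scans[best_week].trait,
            ci_method=ci_method,
        )
        summary = next(s for s in best if s.chromosome == str(chrom))
        summary.trait = f"{family} ({scans[best_week].trait})"
        summary.weeks = sorted(sig_weeks)
        out.append(summary)
    return out
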