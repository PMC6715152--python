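"""Integration of differential expression with seed/occupancy evidence.

Joins a knockout-vs-control DE table with the seed-site table and CLIP site
depths, then computes the de-repression statistics: ECDF shift of log2
fold-changes between gene classes (Kolmogorov–Smirnov), Mann–Whitney depth by
DE direction, a pre-ranked gene-set enrichment score, tiered target calls, and
gene-signature intersections.

Gene classes mirror the standard de-repression analysis: NO_SEED background
(no 7mer/8mer 3'UTR seed match), SEED_3UTR, its CLIP-supported subset
(site depth >= depth_min), a TargetScan-prediction flag, and genes whose only
sites sit in the 5'UTR/CDS.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import GeneDepth, InsufficientDataError
from .seedscan import SeedSite
from .transcriptome import THREE_UTR

log = logging.getLogger(__name__)

NO_SEED = "NO_SEED"
SEED_3UTR = "SEED_3UTR"
SEED_3UTR_AHC5 = "SEED_3UTR_AHC5"
TARGETSCAN = "TARGETSCAN"
SEED_5CDS_ONLY = "SEED_5CDS_ONLY"

UP, DOWN, NS = "UP", "DOWN", "NS"
TIER_NONE, TIER_SEED, TIER_BOUND, TIER_HIGH = (
    "NONE", "SEED_ONLY", "AHC_BOUND", "HIGH_CONFIDENCE_DIRECT")

DE_COLUMNS = ("gene_id", "mean_rpm", "log2fc", "p", "padj")


class SchemaError(ValueError):
    pass


@dataclass
class Config:
    """Analysis thresholds.

    depth_min: minimum CLIP site depth for AHC support (reads).
    p_de:      DE p-value gate for direction calls and the depth comparison.
    p_sig:     looser DE gate used for signature intersections.
    rpm_min:   expressed-gene filter, mean reads-per-million.
    use_padj:  gate on adjusted instead of raw p-values.
    """

    depth_min: int = 5
    p_de: float = 0.05
    p_sig: float = 0.1
    rpm_min: float = 5.0
    use_padj: bool = False

    def __post_init__(self) -> None:
        if min(self.depth_min, self.p_de, self.p_sig, self.rpm_min) <= 0:
            raise ValueError("all thresholds must be > 0")

    def pcol(self) -> str:
        return "padj" if self.use_padj else "p"


def load_de_table(stream: str | TextIO, config: Config | None = None) -> pd.DataFrame:
    """Read the DE TSV and keep expressed genes (mean_rpm >= rpm_min)."""
    config = config or Config()
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    df = pd.read_csv(handle, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"DE table missing columns: {missing}")
    dup = df.loc[df["gene_id"].duplicated(), "gene_id"]
    if len(dup):
        raise SchemaError(f"duplicate gene_id in DE table: {sorted(set(dup))[:5]}")
    for c in ("p", "padj"):
        bad = df[(df[c] < 0) | (df[c] > 1)]
        if len(bad):
            raise SchemaError(f"{c} outside [0,1] for {len(bad)} genes")
    df = df[df["mean_rpm"] >= config.rpm_min].reset_index(drop=True)
    return df


def classify_genes(de: pd.DataFrame, sites: Sequence[SeedSite],
                   gene_depths: Mapping[str, GeneDepth],
                   targetscan: Iterable[str] | None = None,
                   config: Config | None = None) -> pd.DataFrame:
    """Per expressed gene: primary class, flags and site depths.

    Primary classes NO_SEED / SEED_3UTR are mutually exclusive and driven by
    3'UTR sites only; SEED_3UTR_AHC5 marks the depth-supported subset;
    SEED_5CDS_ONLY flags genes with 5'UTR/CDS sites but no 3'UTR site;
    TARGETSCAN flags external predictions intersected with expressed genes.
    """
    config = config or Config()
    seed3 = {s.gene_id for s in sites if s.region == THREE_UTR}
    seed5 = {s.gene_id for s in sites if s.region != THREE_UTR}
    ts_set = set(targetscan or ())
    unknown = ts_set - set(de["gene_id"])
    if unknown:
        log.info("%d TargetScan genes absent from expressed set; ignored", len(unknown))

    rows = []
    for gid in de["gene_id"]:
        gd = gene_depths.get(gid, GeneDepth())
        d3 = gd.depth_3utr if gd.depth_3utr is not None else 0
        d5 = gd.depth_5cds if gd.depth_5cds is not None else 0
        has3 = gid in seed3
        rows.append({
            "gene_id": gid,
            "gene_class": SEED_3UTR if has3 else NO_SEED,
            "seed_3utr": has3,
            "ahc5": has3 and d3 >= config.depth_min,
            "seed_5cds_only": (gid in seed5) and not has3,
            "targetscan": gid in ts_set,
            "depth_3utr": d3,
            "depth_5cds": d5,
        })
    return pd.DataFrame(rows,
                        columns=["gene_id", "gene_class", "seed_3utr", "ahc5",
                                 "seed_5cds_only", "targetscan", "depth_3utr",
                                 "depth_5cds"])


def _class_mask(classes: pd.DataFrame, label: str) -> pd.Series:
    if label == NO_SEED:
        return classes["gene_class"] == NO_SEED
    if label == SEED_3UTR:
        return classes["seed_3utr"]
    if label == SEED_3UTR_AHC5:
        return classes["ahc5"]
    if label == TARGETSCAN:
        return classes["targetscan"]
    if label == SEED_5CDS_ONLY:
        return classes["seed_5cds_only"]
    raise KeyError(f"unknown gene class {label!r}")


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted sample points and the nondecreasing step heights 1/n..1."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


@dataclass
class CdfShiftResult:
    class_label: str
    background_label: str
    n_class: int
    n_background: int
    ks_d: float
    ks_p: float
    median_shift: float
    ecdf_class: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    ecdf_background: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


def cdf_shift(de: pd.DataFrame, classes: pd.DataFrame,
              class_pairs: Sequence[tuple[str, str]] | None = None
              ) -> dict[tuple[str, str], CdfShiftResult]:
    """ECDF comparison of log2FC per class against the no-seed background.

    Reports the two-sample KS statistic/p and the median shift
    median(class) - median(background).  No multiple-testing correction is
    applied across pairs (descriptive statistics accompanying the curves).
    """
    if class_pairs is None:
        class_pairs = [(SEED_3UTR, NO_SEED), (SEED_3UTR_AHC5, NO_SEED),
                       (TARGETSCAN, NO_SEED)]
    merged = de.merge(classes, on="gene_id")
    out = {}
    for cls, bg in class_pairs:
        a = merged.loc[_class_mask(merged, cls), "log2fc"].to_numpy(float)
        b = merged.loc[_class_mask(merged, bg), "log2fc"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"class pair ({cls},{bg}): need >= 2 genes per class "
                f"(have {len(a)}, {len(b)})"
            )
        ks = sps.ks_2samp(a, b)
        out[(cls, bg)] = CdfShiftResult(
            class_label=cls, background_label=bg, n_class=len(a),
            n_background=len(b), ks_d=float(ks.statistic), ks_p=float(ks.pvalue),
            median_shift=float(np.median(a) - np.median(b)),
            ecdf_class=ecdf(a), ecdf_background=ecdf(b),
        )
    return out


# -- Mann-Whitney ------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample via the midrank formula (ties get 0.5)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mannwhitney(x: Sequence[float], y: Sequence[float],
                exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for the first sample.

    Exact permutation enumeration (tie-safe) when both samples are at most
    ``exact_max_n``; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("Mann-Whitney needs both groups non-empty")
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        extreme = total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            up = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(up - mu) >= abs(u - mu) - 1e-12:
                extreme += 1
        return u, extreme / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


@dataclass
class DepthDirectionResult:
    scope: str
    n_up: int
    n_down: int
    u: float          # U of the up-regulated group
    p: float
    median_up: float
    median_down: float


def depth_by_direction(de: pd.DataFrame, classes: pd.DataFrame, scope: str,
                       p_thresh: float | None = None,
                       config: Config | None = None) -> DepthDirectionResult:
    """Compare CLIP site depth between up- and down-regulated seed-match genes.

    ``scope=THREE_UTR``: genes with a 3'UTR seed match, depth over 3'UTR sites.
    ``scope="FIVE_CDS"``: genes with 5'UTR/CDS sites but no 3'UTR site, depth
    over those sites.  Groups are genes with p <= p_thresh split by log2FC sign.
    """
    config = config or Config()
    if p_thresh is None:
        p_thresh = config.p_de
    merged = de.merge(classes, on="gene_id")
    if scope == THREE_UTR:
        pool = merged[merged["seed_3utr"]]
        depth_col = "depth_3utr"
    elif scope == "FIVE_CDS":
        pool = merged[merged["seed_5cds_only"]]
        depth_col = "depth_5cds"
    else:
        raise KeyError(f"unknown scope {scope!r}")
    sig = pool[pool[config.pcol()] <= p_thresh]
    up = sig.loc[sig["log2fc"] > 0, depth_col].to_numpy(float)
    down = sig.loc[sig["log2fc"] < 0, depth_col].to_numpy(float)
    if len(up) == 0 or len(down) == 0:
        raise InsufficientDataError(
            f"{scope}: empty direction group (up={len(up)}, down={len(down)})"
        )
    u, p = mannwhitney(up, down)
    return DepthDirectionResult(
        scope=scope, n_up=len(up), n_down=len(down), u=u, p=p,
        median_up=float(np.median(up)), median_down=float(np.median(down)),
    )


# -- pre-ranked enrichment ---------------------------------------------------

@dataclass
class EnrichmentResult:
    es: float
    running_curve: np.ndarray  # length N+1, starts and ends at 0
    hit_positions: list[int]
    perm_p: float | None = None


def enrichment_score(ranked: Sequence[tuple[str, float]],
                     gene_set: Iterable[str],
                     weight_exponent: float = 1.0,
                     n_perm: int = 0,
                     seed: int | None = None) -> EnrichmentResult:
    """Classic weighted running-sum enrichment score on a pre-ranked list.

    Hits step up by abs(score)**w normalized over hit scores; misses step down by
    1/(N - n_hits).  ES is the signed largest absolute excursion.  With
    ``n_perm`` > 0 a gene-label permutation p-value is attached (hit positions
    resampled uniformly).
    """
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    scores = np.array([s for _, s in ranked], float)
    gene_set = set(gene_set)
    hit = np.array([g in gene_set for g in genes])
    n_hits = int(hit.sum())
    n = len(genes)
    if n_hits == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")

    def _curve(hit_mask: np.ndarray) -> np.ndarray:
        w = np.abs(scores[hit_mask]) ** weight_exponent
        steps = np.where(hit_mask, 0.0, -1.0 / (n - hit_mask.sum()))
        if w.sum() > 0:
            steps[hit_mask] = np.abs(scores[hit_mask]) ** weight_exponent / w.sum()
        else:  # all hit scores zero: fall back to equal hit weights
            steps[hit_mask] = 1.0 / hit_mask.sum()
        return np.concatenate(([0.0], np.cumsum(steps)))

    curve = _curve(hit)
    es = float(curve[np.argmax(np.abs(curve))])

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_at_least = 0
        for _ in range(n_perm):
            mask = np.zeros(n, bool)
            mask[rng.choice(n, n_hits, replace=False)] = True
            c = _curve(mask)
            if abs(c[np.argmax(np.abs(c))]) >= abs(es):
                hits_at_least += 1
        perm_p = (1 + hits_at_least) / (1 + n_perm)

    return EnrichmentResult(es=es, running_curve=curve,
                            hit_positions=list(np.flatnonzero(hit)),
                            perm_p=perm_p)


# -- target calls ------------------------------------------------------------

@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    tier: str
    direction: str


def call_targets(de: pd.DataFrame, classes: pd.DataFrame,
                 config: Config | None = None) -> list[TargetCall]:
    """Tiered evidence per gene.

    SEED_ONLY: a 3'UTR seed match; AHC_BOUND: additionally site depth >=
    depth_min; HIGH_CONFIDENCE_DIRECT: additionally de-repressed in the
    knockout (p <= p_de and log2FC > 0).  Direction is UP/DOWN for p <= p_de
    by fold-change sign (zero fold change is NS), else NS.
    """
    config = config or Config()
    merged = de.merge(classes, on="gene_id")
    pcol = config.pcol()
    calls = []
    for row in merged.itertuples(index=False):
        sig = getattr(row, pcol) <= config.p_de
        if sig and row.log2fc > 0:
            direction = UP
        elif sig and row.log2fc < 0:
            direction = DOWN
        else:
            direction = NS
        if not row.seed_3utr:
            tier = TIER_NONE
        elif not row.ahc5:
            tier = TIER_SEED
        elif direction == UP:
            tier = TIER_HIGH
        else:
            tier = TIER_BOUND
        calls.append(TargetCall(gene_id=row.gene_id, tier=tier, direction=direction))
    return calls


def calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls],
                        columns=["gene_id", "tier", "direction"])


@dataclass
class SignatureResult:
    n_hit: int    # signature genes with a 3'UTR seed match and p <= threshold
    n_up: int
    n_down: int
    table: pd.DataFrame


def intersect_signature(de: pd.DataFrame, classes: pd.DataFrame,
                        signature: Sequence[str],
                        p_thresh: float | None = None,
                        config: Config | None = None) -> SignatureResult:
    """Signature genes that carry a 3'UTR seed match and are differentially
    expressed at ``p_thresh`` (default p_sig), split by fold-change sign."""
    config = config or Config()
    if p_thresh is None:
        p_thresh = config.p_sig
    if not len(signature):
        raise ValueError("signature gene list is empty")
    merged = de.merge(classes, on="gene_id")
    sub = merged[merged["gene_id"].isin(set(signature))
                 & merged["seed_3utr"]
                 & (merged[config.pcol()] <= p_thresh)]
    sub = sub.sort_values("gene_id").reset_index(drop=True)
    n_up = int((sub["log2fc"] > 0).sum())
    n_down = int((sub["log2fc"] < 0).sum())
    cols = ["gene_id", "log2fc", "p", "padj", "depth_3utr"]
    return SignatureResult(n_hit=len(sub), n_up=n_up, n_down=n_down,
                           table=sub[cols])


def read_gene_list(stream: str | TextIO) -> list[str]:
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    return [line.strip() for line in handle if line.strip()
            and not line.startswith("#")]
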