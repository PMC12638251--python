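"""Preranked set-enrichment engine (weighted running-sum KS statistic).

Shared by the gene-set analysis on the screen's dZ ranking and the
metabolite-set analysis on abundance log2 fold changes. Walking a ranked
list, members of the query set ("hits") push a running sum up by their
normalized |stat|^p weight and non-members pull it down by 1/(N - N_hits);
the enrichment score (ES) is the deviation of maximum magnitude. With
weight p = 0 this is the classic two-sample Kolmogorov-Smirnov statistic.

The null is the standard preranked one: random same-size item sets drawn
from the ranked universe (shared across query sets of equal size).
NES = ES / mean(|null ES| of matching sign); the nominal p is the fraction
of the null at least as extreme in the observed direction; the FDR q uses
the NES-histogram ratio estimate (Benjamini-Hochberg on nominal p is
available as an option).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AmbiguityError, ConfigurationError, ScreenDeltaWarning
from .io import AnnotationSetDB


@dataclass(frozen=True)
class RankedList:
    """Items ordered by their statistic in running-sum walk order.

    The walk runs from the most positive statistic downward (the standard
    preranked convention), so a set concentrated among the most negative —
    most depleted/required — statistics receives a *negative* ES. Ties are
    broken lexicographically by item id, so a ranking is a pure function of
    the (id, stat) pairs.
    """

    items: np.ndarray
    stats: np.ndarray

    def __post_init__(self):
        if len(self.items) != len(self.stats):
            raise ConfigurationError("items and stats must align")
        if len(np.unique(self.items)) != len(self.items):
            raise ConfigurationError("ranked list ids must be unique")

    @classmethod
    def from_series(cls, s: pd.Series, *, ascending: bool = False) -> "RankedList":
        frame = s.rename("stat").rename_axis("item").reset_index()
        frame["item"] = frame["item"].astype(str)
        frame = frame.sort_values(
            ["stat", "item"], ascending=[ascending, True], kind="mergesort"
        )
        return cls(frame["item"].to_numpy(), frame["stat"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.items)

    def positions_of(self, ids) -> np.ndarray:
        lookup = {item: i for i, item in enumerate(self.items)}
        try:
            return np.array(sorted(lookup[i] for i in ids), dtype=np.intp)
        except KeyError as e:
            raise ConfigurationError(f"item {e.args[0]!r} not in ranked list") from None


def filter_sets(db: AnnotationSetDB, universe, min_size: int,
                max_size: int) -> AnnotationSetDB:
    """Intersect each set with the universe, then keep it iff its used size
    falls in [min_size, max_size]."""
    if min_size < 1 or max_size < min_size:
        raise ConfigurationError("need 1 <= min_size <= max_size")
    uni = set(map(str, universe))
    if not uni:
        raise ConfigurationError("empty universe")
    out = AnnotationSetDB()
    for name, items in db.sets.items():
        used = [i for i in items if i in uni]
        if min_size <= len(used) <= max_size:
            out.add(name, used, db.descriptions.get(name, ""))
    return out


def _hit_weights(abs_stats_p: np.ndarray, hit_pos: np.ndarray,
                 weight_p: float) -> np.ndarray:
    """Normalized hit increments along the last axis; errors on zero mass."""
    w = abs_stats_p[hit_pos]
    mass = w.sum(axis=-1, keepdims=True)
    if weight_p > 0 and np.any(mass == 0):
        raise ConfigurationError(
            "set carries zero |stat|^p mass with p > 0: hit increments undefined"
        )
    if weight_p == 0:
        return np.full_like(w, 1.0, dtype=float) / w.shape[-1]
    return w / mass


def _es_batch(abs_stats_p: np.ndarray, n_items: int, hit_pos: np.ndarray,
              weight_p: float) -> np.ndarray:
    """ES for each row of ``hit_pos`` (shape (m, k), rows sorted ascending).

    The running sum attains its extrema only at a hit (local max candidate)
    or immediately before one (local min candidate); evaluating those 2k
    candidates reproduces the full walk. Sign ties resolve positive.
    """
    m, k = hit_pos.shape
    n_miss = n_items - k
    if n_miss == 0:
        return np.ones(m)
    w = _hit_weights(abs_stats_p, hit_pos, weight_p)
    cumw = np.cumsum(w, axis=1)
    miss_before = (hit_pos - np.arange(k)) / n_miss
    at_hit = cumw - miss_before            # value just after each hit
    before_hit = cumw - w - miss_before    # value just before each hit
    best_pos = at_hit.max(axis=1)
    best_neg = before_hit.min(axis=1)
    return np.where(best_pos >= -best_neg, best_pos, best_neg)


def enrichment_score(ranked: RankedList, set_ids, *, weight_p: float = 1.0):
    """ES, full running-sum array and leading edge for one set.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` has one
    value per ranked position (ending at 0 up to float error) and the
    leading edge is the hit items at/before the positive extremum or
    at/after the negative one.
    """
    if weight_p < 0:
        raise ConfigurationError("weight_p must be >= 0")
    n = len(ranked)
    pos = ranked.positions_of(set_ids)
    if len(pos) == 0:
        raise ConfigurationError("empty set")
    abs_p = np.abs(ranked.stats) ** weight_p
    k = len(pos)
    if k == n:
        w = _hit_weights(abs_p, pos[None, :], weight_p)[0]
        running = np.cumsum(w)
        return 1.0, running, list(ranked.items[pos])
    steps = np.full(n, -1.0 / (n - k))
    steps[pos] = _hit_weights(abs_p, pos[None, :], weight_p)[0]
    running = np.cumsum(steps)
    es = float(_es_batch(abs_p, n, pos[None, :], weight_p)[0])
    if es >= 0:
        peak = int(np.argmax(running))
        leading = [ranked.items[p] for p in pos if p <= peak]
    else:
        trough_val = running[pos] - steps[pos]  # value just before each hit
        # extremum position: the hit whose preceding value is minimal
        i_min = int(np.argmin(trough_val))
        leading = [ranked.items[p] for p in pos[i_min:]]
    return es, running, leading


def _null_positions(rng: np.random.Generator, n_items: int, size: int,
                    n_perm: int) -> np.ndarray:
    """n_perm random same-size position sets, rows sorted."""
    keys = rng.random((n_perm, n_items))
    pos = np.argpartition(keys, size - 1, axis=1)[:, :size]
    return np.sort(pos, axis=1)


def _exhaustive_positions(n_items: int, size: int) -> np.ndarray:
    n_comb = math.comb(n_items, size)
    if n_comb > 200_000:
        raise ConfigurationError(
            f"exhaustive null over C({n_items},{size}) = {n_comb} sets is too large"
        )
    return np.array(list(itertools.combinations(range(n_items), size)), dtype=np.intp)


#: slack when comparing enrichment scores: exact ties are structural (every
#: set whose hits all precede the same number of misses scores 1 - m/n_miss)
#: and must not be split by accumulation rounding
_ES_TIE_TOL = 1e-12


def _nominal_p(es: float, null_es: np.ndarray) -> float:
    """Fraction of the null at least as extreme in the observed direction."""
    if es >= 0:
        return float(np.mean(null_es >= es - _ES_TIE_TOL))
    return float(np.mean(null_es <= es + _ES_TIE_TOL))


def _nes(es: float, null_es: np.ndarray):
    same = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
    if len(same) == 0:
        return np.nan
    return es / np.mean(np.abs(same))


def preranked_enrichment(ranked: RankedList, db: AnnotationSetDB, *,
                         weight_p: float = 1.0, n_perm: int = 1000,
                         seed: int | None = None, exhaustive: bool = False,
                         fdr_method: str = "gsea") -> pd.DataFrame:
    """Score every set of an already size-filtered database.

    The null for each set size is one shared batch of random same-size item
    sets from the ranked universe (seeded), or every distinct same-size set
    when ``exhaustive``. Results are sorted by NES ascending (most depleted
    sets first), ties by set name.
    """
    if not exhaustive:
        if n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100 (or use exhaustive=True)")
        if seed is None:
            raise ConfigurationError("a seed is required for the permutation null")
    if fdr_method not in ("gsea", "bh"):
        raise ConfigurationError(f"unknown fdr_method {fdr_method!r}")
    n = len(ranked)
    abs_p = np.abs(ranked.stats) ** weight_p
    rng = np.random.default_rng(seed)

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, items in db.sets.items():
        pos = ranked.positions_of(items)
        k = len(pos)
        if k > n:
            raise ConfigurationError(f"set {name!r} larger than the universe")
        es, _, leading = enrichment_score(ranked, items, weight_p=weight_p)
        if k not in null_by_size:
            perm_pos = (_exhaustive_positions(n, k) if exhaustive
                        else _null_positions(rng, n, k, n_perm))
            null_by_size[k] = _es_batch(abs_p, n, perm_pos, weight_p)
        null_es = null_by_size[k]
        nes = _nes(es, null_es)
        if not np.isfinite(nes):
            warnings.warn(
                f"set {name!r}: no null ES of matching sign at this n_perm; "
                "NES reported as missing",
                ScreenDeltaWarning,
                stacklevel=2,
            )
        rows.append(
            {
                "set_name": name,
                "size_used": k,
                "es": es,
                "nes": nes,
                "p_nominal": _nominal_p(es, null_es),
                "leading_edge": leading,
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_name", "size_used", "es", "nes", "p_nominal",
                       "leading_edge"]
    )
    if len(result):
        if fdr_method == "bh":
            from statsmodels.stats.multitest import multipletests

            result["q_fdr"] = multipletests(result["p_nominal"], method="fdr_bh")[1]
        else:
            result["q_fdr"] = _gsea_fdr(result["nes"].to_numpy(), null_by_size,
                                        {r["set_name"]: r["size_used"] for r in rows})
        result = result.sort_values(
            ["nes", "set_name"], kind="mergesort", na_position="last"
        ).reset_index(drop=True)
    else:
        result["q_fdr"] = pd.Series(dtype=float)
    return result[["set_name", "size_used", "es", "nes", "p_nominal",
                   "q_fdr", "leading_edge"]]


def _gsea_fdr(obs_nes: np.ndarray, null_by_size: dict[int, np.ndarray],
              size_of: dict[str, int]) -> np.ndarray:
    """NES-histogram ratio FDR: (null tail fraction) / (observed tail
    fraction), per sign, clipped to [0, 1]."""
    null_nes = []
    for null_es in null_by_size.values():
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        if len(pos):
            null_nes.append(pos / np.mean(pos))
        if len(neg):
            null_nes.append(neg / np.mean(np.abs(neg)))
    pooled = np.concatenate(null_nes) if null_nes else np.array([])
    finite_obs = obs_nes[np.isfinite(obs_nes)]
    q = np.full(len(obs_nes), np.nan)
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_side = pooled[pooled >= 0]
            obs_side = finite_obs[finite_obs >= 0]
            num = np.mean(null_side >= nes) if len(null_side) else 0.0
            den = np.mean(obs_side >= nes) if len(obs_side) else np.nan
        else:
            null_side = pooled[pooled < 0]
            obs_side = finite_obs[finite_obs < 0]
            num = np.mean(null_side <= nes) if len(null_side) else 0.0
            den = np.mean(obs_side <= nes) if len(obs_side) else np.nan
        q[i] = min(1.0, num / den) if den and np.isfinite(den) else np.nan
    return q


def build_metabolite_db(pathway_membership: pd.DataFrame,
                        manual_sets: AnnotationSetDB | None = None,
                        id_map: pd.DataFrame | None = None
                        ) -> tuple[AnnotationSetDB, dict]:
    """Assemble a metabolite-set database from pathway membership.

    ``pathway_membership`` has columns (pathway_id, pathway_name,
    compound_id); ``id_map`` has (measured_name, compound_id) and translates
    compound ids into the names under which metabolites were actually
    measured. Measured names lacking a compound id, and compounds never
    measured, are excluded and listed in the report. Manual sets are
    appended last and override on name collision with a warning.

    Returns ``(db, report)`` with report keys ``unmapped_measured`` and
    ``unused_compounds``.
    """
    need = {"pathway_id", "pathway_name", "compound_id"}
    if pathway_membership.empty or not need.issubset(pathway_membership.columns):
        raise ConfigurationError(
            f"membership table needs non-empty columns {sorted(need)}"
        )
    report = {"unmapped_measured": [], "unused_compounds": []}
    if id_map is not None:
        dup = id_map.groupby("measured_name")["compound_id"].nunique()
        offenders = dup.index[dup > 1].tolist()
        if offenders:
            raise AmbiguityError(
                f"measured name(s) mapped to multiple compound ids: {offenders}"
            )
        has_id = id_map["compound_id"].notna() & (id_map["compound_id"].astype(str) != "")
        report["unmapped_measured"] = sorted(
            id_map.loc[~has_id, "measured_name"].astype(str)
        )
        compound_to_measured: dict[str, list[str]] = {}
        for _, row in id_map[has_id].iterrows():
            compound_to_measured.setdefault(
                str(row["compound_id"]), []
            ).append(str(row["measured_name"]))
    else:
        compound_to_measured = None

    db = AnnotationSetDB()
    used_compounds: set[str] = set()
    for pname, grp in pathway_membership.groupby("pathway_name", sort=False):
        compounds = list(dict.fromkeys(grp["compound_id"].astype(str)))
        if compound_to_measured is None:
            items = compounds
        else:
            items = []
            for c in compounds:
                if c in compound_to_measured:
                    items.extend(compound_to_measured[c])
                    used_compounds.add(c)
        if items:
            db.add(pname, items, str(grp["pathway_id"].iloc[0]))
    if compound_to_measured is not None:
        report["unused_compounds"] = sorted(
            set(pathway_membership["compound_id"].astype(str)) - used_compounds
        )
    if manual_sets is not None:
        for name, items in manual_sets.sets.items():
            if name in db:
                warnings.warn(
                    f"manual set {name!r} overrides a pathway set",
                    ScreenDeltaWarning,
                    stacklevel=2,
                )
            db.add(name, items, manual_sets.descriptions.get(name, ""),
                   override=True)
    return db, report


class PrerankedEnrichment:
    """Model: preranked enrichment of a set database against a ranked list.

    Filters the database against the ranked universe on construction;
    :meth:`fit` runs the permutation engine and returns
    :class:`EnrichmentResults`.
    """

    def __init__(self, ranked: RankedList | pd.Series, db: AnnotationSetDB, *,
                 min_size: int = 2, max_size: int = 50, weight_p: float = 1.0):
        if isinstance(ranked, pd.Series):
            ranked = RankedList.from_series(ranked)
        self.ranked = ranked
        self.weight_p = float(weight_p)
        self.db = filter_sets(db, ranked.items, min_size, max_size)
        self.min_size, self.max_size = min_size, max_size

    def fit(self, *, n_perm: int = 1000, seed: int | None = None,
            exhaustive: bool = False, fdr_method: str = "gsea"
            ) -> "EnrichmentResults":
        table = preranked_enrichment(
            self.ranked, self.db, weight_p=self.weight_p, n_perm=n_perm,
            seed=seed, exhaustive=exhaustive, fdr_method=fdr_method,
        )
        return EnrichmentResults(self, table)


class EnrichmentResults:
    """Per-set ES/NES/p/q table plus running-sum plotting."""

    def __init__(self, model: PrerankedEnrichment, table: pd.DataFrame):
        self.model = model
        self.table = table

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["leading_edge"] = out["leading_edge"].map(",".join)
        out.to_csv(path, sep="\t", index=False)

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_fdr"] < q]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Preranked set enrichment",
            "=" * 58,
            f"ranked items: {len(self.model.ranked)}   sets scored: {len(self.table)} "
            f"(size {self.model.min_size}-{self.model.max_size}, weight p = {self.model.weight_p:g})",
            "",
            f"{'set':<34s}{'size':>5s}{'NES':>8s}{'p':>8s}{'q':>8s}",
        ]
        for _, r in self.table.head(top).iterrows():
            lines.append(
                f"{r.set_name[:33]:<34s}{int(r.size_used):>5d}{r.nes:>8.3f}"
                f"{r.p_nominal:>8.4f}{r.q_fdr:>8.4f}"
            )
        return "\n".join(lines)

    def plot_running_sum(self, set_name: str, ax=None):
        import matplotlib.pyplot as plt

        if set_name not in self.model.db:
            raise ConfigurationError(f"set {set_name!r} was not scored")
        _, running, _ = enrichment_score(
            self.model.ranked, self.model.db[set_name],
            weight_p=self.model.weight_p,
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.plot(running, lw=1.2, c="#33557f")
        ax.axhline(0.0, lw=0.6, c="grey")
        pos = self.model.ranked.positions_of(self.model.db[set_name])
        ax.vlines(pos, -0.02, 0.02, color="black", lw=0.4)
        ax.set_xlabel("rank")
        ax.set_ylabel("running enrichment")
        ax.set_title(set_name)
        return ax
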