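"""FEP/US free-energy profiles on the energy-gap coordinate.

Two steps turn mapping-potential samples into a reaction profile:

1. *FEP stitching*: the free-energy difference between adjacent lambda
   frames is estimated by Zwanzig exponential averaging,
   ``dG = -kT ln < exp(-(e_map' - e_map)/kT) >_lambda``, and accumulated
   along the schedule to give ``dG_map(lambda_m)``.

2. *Umbrella correction*: within each frame the bias of sampling on the
   mapping potential instead of the adiabatic ground state is removed per
   energy-gap bin,
   ``dG(bin) = dG_map(m) - kT ln < 1_bin exp(-(E_g - e_map)/kT) >_m``,
   and frame contributions to a bin are combined weighted by their sample
   counts in that bin.

Profiles are anchored so the reactant-basin minimum is exactly zero; with
the gap defined as ``eps2 - eps1`` the reactant basin (state 1 lower) lies
at positive gap, which the profile records in its anchor tag.  Replica-level
scatter provides the standard errors.

All exponentials are evaluated in log space (`scipy.special.logsumexp`);
energy gaps of tens of kcal/mol would otherwise overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import EVBParameters, ground_state_energy
from .sampler import SampleSet

__all__ = [
    "FreeEnergyProfile",
    "ReactionThermo",
    "NoBarrierError",
    "MissingBinsError",
    "fep_increment",
    "map_free_energies",
    "us_profile",
    "replica_profiles",
    "extract_thermo",
    "replica_errors",
    "analyze",
]


class NoBarrierError(ValueError):
    """The profile has no interior maximum between the two basins."""


class MissingBinsError(ValueError):
    """Unsampled bins interrupt the region between the two basins."""


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Binned free energy over the energy-gap coordinate.

    Bins never sampled carry ``nan`` in ``dg`` (missing, not zero); ``sem``
    is ``nan`` where no replica-level estimate exists.  ``anchor`` records
    the anchoring convention: which side of the gap axis is the reactant
    basin ("high" or "low") whose minimum was set to zero.
    """

    bin_edges: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    sem: np.ndarray
    anchor: str = "unanchored"
    #: gap values near which the basins are expected: the mean gap of the
    #: lambda=0 / lambda=1 ensembles (estimator) or the gap at the diabatic
    #: minima (oracle).  nan when unknown; basin location then falls back to
    #: splitting the populated range in thirds.
    reactant_hint: float = float("nan")
    product_hint: float = float("nan")

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin_edges must be strictly increasing, length >= 2")
        for name in ("dg", "counts", "sem"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(e) - 1,):
                raise ValueError(f"{name} must have one value per bin")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "bin_edges", e)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.dg) & (self.counts > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.centers, "dG": self.dg, "count": self.counts, "sem": self.sem}
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# anchor={self.anchor}\n")
            fh.write(f"# bin_width={self.bin_edges[1] - self.bin_edges[0]:.10g}\n")
            fh.write(f"# reactant_hint={self.reactant_hint:.10g}\n")
            fh.write(f"# product_hint={self.product_hint:.10g}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FreeEnergyProfile":
        meta = {"anchor": "unanchored", "bin_width": None,
                "reactant_hint": float("nan"), "product_hint": float("nan")}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                key = key.strip()
                if key == "anchor":
                    meta[key] = val.strip()
                elif key in meta:
                    meta[key] = float(val)
        df = pd.read_csv(path, sep="\t", comment="#")
        centers = df["bin_center"].to_numpy()
        w = meta["bin_width"] if meta["bin_width"] is not None else float(np.diff(centers).min())
        edges = np.append(centers - w / 2, centers[-1] + w / 2)
        return cls(
            edges,
            df["dG"].to_numpy(),
            df["count"].to_numpy(),
            df["sem"].to_numpy(),
            meta["anchor"],
            meta["reactant_hint"],
            meta["product_hint"],
        )


@dataclass(frozen=True)
class ReactionThermo:
    """Activation and reaction free energies extracted from a profile."""

    dg_act: float
    dg_rxn: float
    err_act: float = float("nan")
    err_rxn: float = float("nan")
    reactant_gap: float = float("nan")
    ts_gap: float = float("nan")
    product_gap: float = float("nan")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


# --------------------------------------------------------------------------
# FEP stitching
# --------------------------------------------------------------------------


def fep_increment(e_map_i: np.ndarray, e_map_next: np.ndarray, kT: float) -> float:
    """Zwanzig free-energy step between adjacent mapping potentials.

    ``e_map_i`` and ``e_map_next`` are the two mapping energies evaluated on
    the *same* frame-i configurations; returns
    ``-kT ln < exp(-(e_next - e_i)/kT) >``.  Exact for a constant shift.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    w = np.asarray(e_map_next, dtype=float) - np.asarray(e_map_i, dtype=float)
    if w.size == 0:
        raise ValueError("empty sample set")
    return float(-kT * (logsumexp(-w / kT) - np.log(w.size)))


def map_free_energies(frames: Sequence[dict], kT: float, symmetric: bool = True) -> np.ndarray:
    """Cumulative dG_map(lambda_m) along the schedule, anchored at frame 0.

    `frames` is an ordered sequence of dicts with keys ``lam``, ``eps1``,
    ``eps2`` (arrays).  The forward step m -> m+1 uses frame-m
    configurations, on which the perturbation is
    ``(lam_{m+1} - lam_m) * (eps2 - eps1)``.  With ``symmetric=True``
    (default) each step averages the forward estimate with the reverse
    estimate from frame m+1, which cancels the leading finite-sample bias
    of one-sided exponential averaging.
    """
    g = np.zeros(len(frames))
    for m in range(len(frames) - 1):
        dlam = frames[m + 1]["lam"] - frames[m]["lam"]
        w_fwd = dlam * (frames[m]["eps2"] - frames[m]["eps1"])
        step = -kT * (logsumexp(-w_fwd / kT) - np.log(w_fwd.size))
        if symmetric:
            w_bwd = dlam * (frames[m + 1]["eps2"] - frames[m + 1]["eps1"])
            back = -kT * (logsumexp(w_bwd / kT) - np.log(w_bwd.size))
            step = 0.5 * (step - back)
        g[m + 1] = g[m] + step
    return g


# --------------------------------------------------------------------------
# umbrella correction and binning
# --------------------------------------------------------------------------


def _frames_of(df: pd.DataFrame) -> List[dict]:
    out = []
    for m, sub in df.groupby("frame", sort=True):
        out.append(
            {
                "lam": float(sub["lam"].iloc[0]),
                "eps1": sub["eps1"].to_numpy(),
                "eps2": sub["eps2"].to_numpy(),
                "e_map": sub["e_map"].to_numpy(),
            }
        )
    return out


def _locate_basins(
    dg: np.ndarray,
    counts: np.ndarray,
    centers: np.ndarray,
    side: str,
    hint_r: float = float("nan"),
    hint_p: float = float("nan"),
) -> tuple:
    """Indices of the reactant and product basin minima.

    With basin hints available, each minimum is the lowest populated bin
    within a window of half the hint separation around its hint (nearest
    populated bin if the window is empty).  Without hints, the populated
    range is split into thirds and the minima taken from the outer groups,
    reactant on `side` ("high"/"low" gap).
    """
    pop = np.flatnonzero(np.isfinite(dg) & (counts > 0))
    if pop.size == 0:
        raise ValueError("cannot locate basins of an empty profile")
    if np.isfinite(hint_r) and np.isfinite(hint_p) and hint_r != hint_p:
        half = 0.25 * abs(hint_r - hint_p)

        def pick(hint):
            cand = pop[np.abs(centers[pop] - hint) <= half]
            if cand.size == 0:
                cand = pop[[int(np.argmin(np.abs(centers[pop] - hint)))]]
            # ignore rare-excursion bins: their estimates are dominated by a
            # handful of extreme samples and would pull the basin minimum out
            # into the tail
            solid = cand[counts[cand] >= 0.05 * counts[cand].max()]
            if solid.size:
                cand = solid
            return int(cand[np.argmin(dg[cand])])

        return pick(hint_r), pick(hint_p)
    groups = [g for g in np.array_split(pop, 3) if g.size]
    r_grp = groups[-1] if side == "high" else groups[0]
    p_grp = groups[0] if side == "high" else groups[-1]
    return int(r_grp[np.argmin(dg[r_grp])]), int(p_grp[np.argmin(dg[p_grp])])


def _anchor_shift(
    dg: np.ndarray,
    counts: np.ndarray,
    centers: np.ndarray,
    side: str,
    hint_r: float = float("nan"),
    hint_p: float = float("nan"),
) -> float:
    if np.isfinite(hint_r) and (not np.isfinite(hint_p) or hint_p == hint_r):
        # degenerate hints (e.g. a single-frame, single-basin profile):
        # the reactant basin is the only basin
        pop = np.isfinite(dg) & (counts > 0)
        if not pop.any():
            raise ValueError("cannot anchor an empty profile")
        return float(np.min(dg[pop]))
    r_idx, _ = _locate_basins(dg, counts, centers, side, hint_r, hint_p)
    return float(dg[r_idx])


def _single_profile(
    df: pd.DataFrame, params: EVBParameters, kT: float, bin_edges: np.ndarray
) -> "FreeEnergyProfile":
    frames = _frames_of(df)
    g_map = map_free_energies(frames, kT)
    n_bins = len(bin_edges) - 1
    log_num = np.full((len(frames), n_bins), -np.inf)
    n_mb = np.zeros((len(frames), n_bins))
    for m, fr in enumerate(frames):
        gap = fr["eps2"] - fr["eps1"]
        e_g = ground_state_energy(fr["eps1"], fr["eps2"], params)
        a = -(np.asarray(e_g) - fr["e_map"]) / kT
        idx = np.digitize(gap, bin_edges) - 1
        ok = (idx >= 0) & (idx < n_bins)
        n_frame = len(gap)
        for b in np.unique(idx[ok]):
            sel = ok & (idx == b)
            n_mb[m, b] = sel.sum()
            log_num[m, b] = logsumexp(a[sel]) - np.log(n_frame)
    dg_mb = g_map[:, None] - kT * log_num  # +inf where bin empty in frame
    counts = n_mb.sum(axis=0)
    dg = np.full(n_bins, np.nan)
    for b in range(n_bins):
        w = n_mb[:, b]
        m = w > 0
        if m.any():
            dg[b] = np.sum(w[m] * dg_mb[m, b]) / w[m].sum()
    # reactant side from the lambda=0 ensemble: where state 1 is the lower diabat
    hint_r = float(np.mean(frames[0]["eps2"] - frames[0]["eps1"]))
    hint_p = float(np.mean(frames[-1]["eps2"] - frames[-1]["eps1"]))
    side = "high" if hint_r > 0 else "low"
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    shift = _anchor_shift(dg, counts, centers, side, hint_r, hint_p)
    return FreeEnergyProfile(
        bin_edges=bin_edges,
        dg=dg - shift,
        counts=counts,
        sem=np.full(n_bins, np.nan),
        anchor=f"reactant={side}",
        reactant_hint=hint_r,
        product_hint=hint_p,
    )


def _auto_edges(gaps: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(gaps.min() / bin_width) * bin_width
    hi = np.ceil(gaps.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    return lo + bin_width * np.arange(n + 1)


def replica_profiles(
    samples: SampleSet,
    params: EVBParameters,
    kT: float,
    bin_edges: Optional[np.ndarray] = None,
    bin_width: float = 2.0,
) -> Dict[int, FreeEnergyProfile]:
    """Anchored FEP/US profile of each replica on a common set of bins."""
    if bin_edges is None:
        gaps = samples.data["eps2"].to_numpy() - samples.data["eps1"].to_numpy()
        bin_edges = _auto_edges(gaps, bin_width)
    return {
        r: _single_profile(samples.for_replica(r), params, kT, np.asarray(bin_edges, float))
        for r in samples.replicas
    }


def us_profile(
    samples: SampleSet,
    params: EVBParameters,
    kT: float,
    bin_edges: Optional[np.ndarray] = None,
    bin_width: float = 2.0,
    min_replicas: int = 1,
) -> FreeEnergyProfile:
    """Pooled FEP/US profile across replicas with per-bin standard errors.

    Each replica is estimated and anchored independently; per bin, the
    pooled value is the mean over the replicas that populated it and ``sem``
    the standard error of that mean (``nan`` with fewer than two replicas).
    Bins populated by fewer than `min_replicas` replicas are reported
    missing.  The pooled profile is re-anchored so the reactant-basin
    minimum is exactly zero.
    """
    per = replica_profiles(samples, params, kT, bin_edges, bin_width)
    return _pool_profiles(list(per.values()), min_replicas)


def _pool_profiles(profiles: List[FreeEnergyProfile], min_replicas: int = 1) -> FreeEnergyProfile:
    edges = profiles[0].bin_edges
    stack = np.stack([p.dg for p in profiles])
    pop = np.stack([p.populated for p in profiles])
    counts = np.stack([p.counts for p in profiles]).sum(axis=0)
    n_pop = pop.sum(axis=0)
    keep = n_pop >= max(min_replicas, 1)
    dg = np.full(stack.shape[1], np.nan)
    sem = np.full(stack.shape[1], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(pop, stack, np.nan)
        dg[keep] = np.nanmean(masked[:, keep], axis=0)
        multi = keep & (n_pop >= 2)
        sem[multi] = np.nanstd(masked[:, multi], axis=0, ddof=1) / np.sqrt(n_pop[multi])
    counts = np.where(keep, counts, 0.0)
    side = profiles[0].anchor.split("=")[-1]
    hint_r = float(np.mean([p.reactant_hint for p in profiles]))
    hint_p = float(np.mean([p.product_hint for p in profiles]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    shift = _anchor_shift(dg, counts, centers, side, hint_r, hint_p)
    return FreeEnergyProfile(
        edges,
        dg - shift,
        counts,
        sem,
        anchor=f"reactant={side}",
        reactant_hint=hint_r,
        product_hint=hint_p,
    )


# --------------------------------------------------------------------------
# thermodynamic extraction
# --------------------------------------------------------------------------


def extract_thermo(
    profile: FreeEnergyProfile, reactant_side: Optional[str] = None
) -> ReactionThermo:
    """Locate the two basins and the transition state of a profile.

    The basin minima are located from the profile's basin hints when it
    carries them (lowest populated bin near each hint); otherwise the
    populated bins are split into three contiguous groups along the gap
    axis and the reactant minimum is the lowest bin in the group on
    `reactant_side` ("high"/"low"; defaults to the profile's anchor tag,
    falling back to "low"), the product minimum the lowest bin in the
    opposite group.  The transition state is the highest bin strictly
    between the minima (ties broken toward gap = 0).

    Raises :class:`MissingBinsError` if unsampled bins interrupt the
    interior, and :class:`NoBarrierError` if no interior bin rises above
    both basins (monotone profile).
    """
    locs = _locate_features(profile, reactant_side)
    return _thermo_at(profile, locs)


def _locate_features(
    profile: FreeEnergyProfile, reactant_side: Optional[str] = None
) -> tuple:
    """Bin indices of (reactant minimum, transition state, product minimum)."""
    side = reactant_side or (
        profile.anchor.split("=")[-1] if "=" in profile.anchor else "low"
    )
    if side not in ("low", "high"):
        raise ValueError(f"reactant_side must be 'low' or 'high', got {side!r}")
    pop = np.flatnonzero(profile.populated)
    if pop.size < 3:
        raise NoBarrierError("profile has fewer than three populated bins")
    dg = profile.dg
    r_idx, p_idx = _locate_basins(
        dg,
        profile.counts,
        profile.centers,
        side,
        profile.reactant_hint if reactant_side is None else float("nan"),
        profile.product_hint if reactant_side is None else float("nan"),
    )
    lo, hi = min(r_idx, p_idx), max(r_idx, p_idx)
    interior = np.arange(lo + 1, hi)
    if interior.size == 0:
        raise NoBarrierError("basins are adjacent; no interior bins")
    unsampled = interior[~profile.populated[interior]]
    if unsampled.size:
        raise MissingBinsError(
            f"{unsampled.size} unsampled bin(s) between the basins "
            f"(gap ~ {profile.centers[unsampled[0]]:.3g}); refusing to bridge them"
        )
    ts_val = dg[interior].max()
    if ts_val <= max(dg[r_idx], dg[p_idx]):
        raise NoBarrierError("no interior maximum above both basins (monotone profile)")
    ties = interior[dg[interior] == ts_val]
    ts_idx = int(ties[np.argmin(np.abs(profile.centers[ties]))])
    return r_idx, ts_idx, p_idx


def _thermo_at(profile: FreeEnergyProfile, locs: tuple) -> ReactionThermo:
    """Thermodynamics read off a profile at fixed feature bin indices."""
    r_idx, ts_idx, p_idx = locs
    if not all(profile.populated[[r_idx, ts_idx, p_idx]]):
        raise MissingBinsError("a feature bin is unpopulated in this profile")
    dg, sem = profile.dg, profile.sem

    def _err(i, j):
        if np.isfinite(sem[i]) and np.isfinite(sem[j]):
            return float(np.hypot(sem[i], sem[j]))
        return float("nan")

    return ReactionThermo(
        dg_act=float(dg[ts_idx] - dg[r_idx]),
        dg_rxn=float(dg[p_idx] - dg[r_idx]),
        err_act=_err(ts_idx, r_idx),
        err_rxn=_err(p_idx, r_idx),
        reactant_gap=float(profile.centers[r_idx]),
        ts_gap=float(profile.centers[ts_idx]),
        product_gap=float(profile.centers[p_idx]),
    )


def replica_errors(thermos: Sequence[ReactionThermo]) -> ReactionThermo:
    """Pool per-replica thermodynamics: mean and standard error of the mean."""
    if len(thermos) == 0:
        raise ValueError("no replicas to pool")
    act = np.array([t.dg_act for t in thermos])
    rxn = np.array([t.dg_rxn for t in thermos])
    if len(thermos) < 2:
        warnings.warn("fewer than 2 replicas: pooled errors are undefined")
        err_act = err_rxn = float("nan")
    else:
        err_act = float(np.std(act, ddof=1) / np.sqrt(len(act)))
        err_rxn = float(np.std(rxn, ddof=1) / np.sqrt(len(rxn)))
    return ReactionThermo(
        dg_act=float(act.mean()),
        dg_rxn=float(rxn.mean()),
        err_act=err_act,
        err_rxn=err_rxn,
        reactant_gap=float(np.mean([t.reactant_gap for t in thermos])),
        ts_gap=float(np.mean([t.ts_gap for t in thermos])),
        product_gap=float(np.mean([t.product_gap for t in thermos])),
    )


def analyze(
    samples: SampleSet,
    params: EVBParameters,
    kT: float,
    bin_edges: Optional[np.ndarray] = None,
    bin_width: float = 2.0,
    min_replicas: int = 1,
):
    """Full estimator chain: pooled profile, per-replica thermo, pooled thermo.

    Returns ``(profile, per_replica_thermos, pooled_thermo)``.  The basin
    and transition-state *locations* are identified once on the pooled
    profile, where the noise is lowest; each replica's thermodynamics is
    then read at those fixed bins (selecting an extremum independently per
    replica would bias every replica high through the max operation).
    Replicas missing one of the feature bins are dropped with a warning.
    """
    per = replica_profiles(samples, params, kT, bin_edges, bin_width)
    profile = _pool_profiles(list(per.values()), min_replicas)
    locs = _locate_features(profile)
    thermos = []
    for r, prof in per.items():
        try:
            thermos.append(_thermo_at(prof, locs))
        except MissingBinsError as exc:
            warnings.warn(f"replica {r}: {exc}")
    if not thermos:
        raise NoBarrierError("no replica populated the pooled feature bins")
    pooled_thermo = replica_errors(thermos)
    return profile, thermos, pooled_thermo
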