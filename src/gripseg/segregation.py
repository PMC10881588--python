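"""System segregation and intra-/inter-network connectivity.

Given a prepared Fisher-z connectivity matrix and a partition of its
regions into networks, system segregation contrasts mean within-network
connectivity (Z̄w) with mean between-network connectivity (Z̄b):

    Segregation = (Z̄w - Z̄b) / Z̄w

computed globally (pooling all within-network edges across networks against
all between-network edges) and per network (edges inside the network
against edges linking it to the rest of the brain).  All means run over
unordered region pairs, each counted once; edges that were negative before
preparation contribute 0 to the means rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix


@dataclass(frozen=True)
class NetworkPartition:
    """Region -> network assignment over an ordered set of network labels."""

    assignment: dict[str, str]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        object.__setattr__(self, "networks", tuple(self.networks))
        used = set(self.assignment.values())
        missing = [n for n in self.networks if n not in used]
        if missing:
            raise ValueError(f"empty network(s): {', '.join(missing)}")
        stray = used - set(self.networks)
        if stray:
            raise ValueError(f"regions assigned to unknown network(s): {sorted(stray)}")

    @classmethod
    def from_assignment(cls, assignment: dict[str, str],
                        networks: tuple[str, ...] | None = None) -> "NetworkPartition":
        if networks is None:
            seen: list[str] = []
            for net in assignment.values():
                if net not in seen:
                    seen.append(net)
            networks = tuple(seen)
        return cls(assignment, networks)

    def regions_of(self, network: str) -> list[str]:
        if network not in self.networks:
            raise KeyError(f"unknown network: {network}")
        return sorted(r for r, n in self.assignment.items() if n == network)

    def size_of(self, network: str) -> int:
        return len(self.regions_of(network))


def read_partition(path, sep: str = "\t") -> NetworkPartition:
    """Two-column table (region_id, network_label) -> partition."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("partition table needs two columns: region_id, network_label")
    region_col, net_col = df.columns[:2]
    assignment = dict(zip(df[region_col].astype(str), df[net_col].astype(str)))
    if len(assignment) != len(df):
        raise ValueError("duplicate region ids in partition table")
    return NetworkPartition.from_assignment(assignment)


def write_partition(p: NetworkPartition, path, sep: str = "\t") -> None:
    rows = [(r, p.assignment[r]) for net in p.networks for r in p.regions_of(net)]
    pd.DataFrame(rows, columns=["region_id", "network_label"]).to_csv(
        path, sep=sep, index=False)


@dataclass(frozen=True)
class SegregationProfile:
    """Per-subject segregation summary.

    ``intra[k]`` equals ``zw[k]`` by construction; ``inter[(k, l)]`` is the
    mean Fisher-z over region pairs spanning networks k and l, keyed with
    k, l in partition network order (k before l).
    """

    subject_id: str
    zw_global: float
    zb_global: float
    seg_global: float
    zw: dict[str, float]
    zb: dict[str, float]
    seg: dict[str, float]
    intra: dict[str, float]
    inter: dict[tuple[str, str], float]


def network_pairs(p: NetworkPartition, network: str) -> list[tuple[str, str]]:
    """All unordered region pairs within a network, lexicographic, each once."""
    regions = p.regions_of(network)
    return list(combinations(regions, 2))


def edge_fc(m: ConnectivityMatrix, pair: tuple[str, str]) -> float:
    """The Fisher-z value at an unordered region pair (symmetric access)."""
    a, b = pair
    return float(m.z[m.index_of(a), m.index_of(b)])


def _labels_for(m: ConnectivityMatrix, p: NetworkPartition) -> np.ndarray:
    unassigned = [r for r in m.region_ids if r not in p.assignment]
    if unassigned:
        raise ValueError(f"regions missing from partition: {unassigned[:5]}")
    return np.array([p.assignment[r] for r in m.region_ids])


def within_between_means(m: ConnectivityMatrix, p: NetworkPartition,
                         scope: str = "global") -> tuple[float, float]:
    """(Z̄w, Z̄b) for one network, or pooled over all networks (scope='global').

    Network scope: Z̄w averages pairs with both regions in the network, Z̄b
    pairs with exactly one.  Global scope: pooled means over all
    within-network and all between-network pairs respectively.
    """
    if not m.prepared:
        raise ValueError("matrix must be prepared (diagonal/negatives zeroed)")
    labels = _labels_for(m, p)
    iu = np.triu_indices(m.n_regions, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = m.z[iu]
    if scope == "global":
        return float(vals[same].mean()), float(vals[~same].mean())
    if scope not in p.networks:
        raise KeyError(f"unknown network: {scope}")
    if p.size_of(scope) < 2:
        raise ValueError(f"network {scope!r} has fewer than 2 regions")
    in_a = labels[iu[0]] == scope
    in_b = labels[iu[1]] == scope
    within = in_a & in_b
    between = in_a ^ in_b
    return float(vals[within].mean()), float(vals[between].mean())


def segregation(zw: float, zb: float, scope: str = "") -> float:
    """(Z̄w - Z̄b) / Z̄w; undefined when Z̄w = 0."""
    if zw == 0.0:
        where = f" for {scope}" if scope else ""
        raise ValueError(f"segregation undefined{where}: mean within-network connectivity is 0")
    return (zw - zb) / zw


def profile_subject(m: ConnectivityMatrix, p: NetworkPartition) -> SegregationProfile:
    """Full segregation profile: global and per-network Z̄w/Z̄b/segregation,
    intra-network means and every pairwise inter-network mean.

    Uses indicator-matrix block sums, so it is O(R^2 K) regardless of
    partition shape.
    """
    if not m.prepared:
        raise ValueError("matrix must be prepared (diagonal/negatives zeroed)")
    labels = _labels_for(m, p)
    nets = p.networks
    if len(nets) < 2:
        raise ValueError("segregation needs at least 2 networks")
    sizes = np.array([np.sum(labels == k) for k in nets], dtype=float)
    if np.any(sizes < 2):
        small = [k for k, s in zip(nets, sizes) if s < 2]
        raise ValueError(f"network(s) with fewer than 2 regions: {small}")

    ind = np.stack([(labels == k).astype(float) for k in nets], axis=1)  # R x K
    block_sum = ind.T @ m.z @ ind                                        # K x K
    # unordered pair counts: n_k(n_k-1)/2 on the diagonal, n_k*n_l off it
    pair_count = np.outer(sizes, sizes)
    np.fill_diagonal(pair_count, sizes * (sizes - 1) / 2.0)
    block_mean = np.empty_like(block_sum)
    diag = np.arange(len(nets))
    block_mean[:] = block_sum / pair_count
    block_mean[diag, diag] = (np.diag(block_sum) / 2.0) / np.diag(pair_count)

    zw = {k: float(block_mean[i, i]) for i, k in enumerate(nets)}
    zb = {}
    for i, k in enumerate(nets):
        cross_sum = block_sum[i, :].sum() - block_sum[i, i]
        cross_n = pair_count[i, :].sum() - pair_count[i, i]
        zb[k] = float(cross_sum / cross_n)
    within_sum = float(np.sum(np.diag(block_sum)) / 2.0)
    within_n = float(np.sum(np.diag(pair_count)))
    iu = np.triu_indices(len(nets), k=1)
    between_sum = float(block_sum[iu].sum())
    between_n = float(pair_count[iu].sum())
    zw_g = within_sum / within_n
    zb_g = between_sum / between_n

    seg = {k: segregation(zw[k], zb[k], scope=k) for k in nets}
    inter = {(nets[i], nets[j]): float(block_mean[i, j])
             for i in range(len(nets)) for j in range(i + 1, len(nets))}
    return SegregationProfile(
        subject_id=m.subject_id,
        zw_global=zw_g, zb_global=zb_g,
        seg_global=segregation(zw_g, zb_g, scope="global"),
        zw=zw, zb=zb, seg=seg, intra=dict(zw), inter=inter,
    )


def profiles_to_frame(profiles: list[SegregationProfile]) -> pd.DataFrame:
    """Long-format table: subject_id, measure_name, value.

    measure_name follows ``seg_global`` / ``seg:<net>`` / ``intra:<net>`` /
    ``inter:<netA>:<netB>`` (plus ``zw_global``/``zb_global`` for bookkeeping).
    """
    rows = []
    for pr in profiles:
        rows.append((pr.subject_id, "seg_global", pr.seg_global))
        rows.append((pr.subject_id, "zw_global", pr.zw_global))
        rows.append((pr.subject_id, "zb_global", pr.zb_global))
        for k, v in pr.seg.items():
            rows.append((pr.subject_id, f"seg:{k}", v))
        for k, v in pr.intra.items():
            rows.append((pr.subject_id, f"intra:{k}", v))
        for (a, b), v in pr.inter.items():
            rows.append((pr.subject_id, f"inter:{a}:{b}", v))
    return pd.DataFrame(rows, columns=["subject_id", "measure_name", "value"])


def edges_to_frame(matrices: list[ConnectivityMatrix], p: NetworkPartition,
                   network: str) -> pd.DataFrame:
    """Per-subject edge values for every pair inside one network (wide table)."""
    pairs = network_pairs(p, network)
    cols = {f"edge:{a}:{b}": [edge_fc(m, (a, b)) for m in matrices] for a, b in pairs}
    return pd.DataFrame(cols, index=pd.Index([m.subject_id for m in matrices],
                                             name="subject_id"))
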