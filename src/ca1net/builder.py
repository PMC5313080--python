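"""Cell placement and distance-binned connectivity generation.

Cells are laid on regular 3D lattices filling their layer volumes (matching
the even within-layer distribution of the biological census).  Connections
between two cell types follow a three-step algorithm: (1) all pre-post
distances are computed in the XY plane only; (2) the target number of
connections is split into radial distance bins according to the presynaptic
type's Gaussian axonal bouton distribution; (3) candidate pairs are assigned
to their bins and each bin's quota is sampled uniformly without replacement.
When a bin holds fewer candidates than its quota, the deficit is reassigned
to the nearest non-exhausted bins (alternating inward/outward), preserving
the total connection count while minimally distorting the distance profile.

Each ordered pair connects at most once; a connection comprises the
experimentally observed number of synapses (1-10) for that type pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import AxonalProfile, NetworkConfig, census

EDGE_COLUMNS = ["pre_gid", "post_gid", "n_syn", "dist_um", "zone", "weight", "delay_ms"]

_PAIR_CHUNK = 2_000_000  # candidate-pair scratch rows per block


@dataclass
class CellPositions:
    """Positions (um) and type labels for every cell, gids 0..N-1.

    Local cells come first in config order; afferent units follow.
    """

    xyz: np.ndarray                  # (n, 3) float
    type_codes: np.ndarray           # (n,) int index into type_names
    type_names: list[str]
    slices: dict[str, slice]         # gid range per population

    def of_type(self, name: str) -> np.ndarray:
        return self.xyz[self.slices[name]]

    def gids_of(self, name: str) -> np.ndarray:
        s = self.slices[name]
        return np.arange(s.start, s.stop)

    @property
    def n_cells(self) -> int:
        return self.xyz.shape[0]


@dataclass
class EdgeList:
    """Generated connections of one or several projections."""

    pre_gid: np.ndarray
    post_gid: np.ndarray
    n_syn: np.ndarray
    dist_um: np.ndarray
    zone: np.ndarray                 # string array
    weight: np.ndarray               # per-connection peak conductance (nS)
    delay_ms: np.ndarray
    pair_labels: np.ndarray = field(default=None)  # "PRE->POST" per edge

    def __len__(self) -> int:
        return self.pre_gid.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre_gid": self.pre_gid, "post_gid": self.post_gid,
            "n_syn": self.n_syn, "dist_um": self.dist_um, "zone": self.zone,
            "weight": self.weight, "delay_ms": self.delay_ms,
        })

    @classmethod
    def empty(cls) -> "EdgeList":
        z = np.empty(0)
        return cls(z.astype(np.int64), z.astype(np.int64), z.astype(np.int32),
                   z.copy(), np.empty(0, dtype=object), z.copy(), z.copy(),
                   np.empty(0, dtype=object))

    @classmethod
    def concat(cls, parts: list["EdgeList"]) -> "EdgeList":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(*[np.concatenate([getattr(p, f) for p in parts])
                     for f in ("pre_gid", "post_gid", "n_syn", "dist_um",
                               "zone", "weight", "delay_ms", "pair_labels")])


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _lattice_dims(n: int, lx: float, ly: float, lz: float) -> tuple[int, int, int]:
    """Integer lattice dimensions closest to the volume's aspect ratio with
    nx*ny*nz >= n."""
    vol = lx * ly * lz
    nz = max(1, round(lz * (n / vol) ** (1.0 / 3.0)))
    m = -(-n // nz)  # ceil
    nx = max(1, round(np.sqrt(m * lx / ly)))
    ny = -(-m // nx)
    return nx, ny, nz


def lattice_positions(n: int, x0: float, x1: float, y0: float, y1: float,
                      z0: float, z1: float) -> np.ndarray:
    """First ``n`` cell-centred lattice sites filling the box, z/y/x-major."""
    if n == 0:
        return np.empty((0, 3))
    lx, ly, lz = x1 - x0, y1 - y0, z1 - z0
    if lx <= 0 or ly <= 0 or lz <= 0:
        raise ValueError("layer volume is zero but cell count is nonzero")
    nx, ny, nz = _lattice_dims(n, lx, ly, lz)
    xs = x0 + (np.arange(nx) + 0.5) * lx / nx
    ys = y0 + (np.arange(ny) + 0.5) * ly / ny
    zs = z0 + (np.arange(nz) + 0.5) * lz / nz
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return pts[:n]


def place_cells(cfg: NetworkConfig) -> CellPositions:
    """Deterministic even placement of all local cells and afferent units."""
    geo = cfg.geometry
    blocks, codes, names, slices = [], [], [], {}
    start = 0
    pops = [(n, t.count, t.layer) for n, t in cfg.cell_types.items()]
    pops += [(n, a.count, a.layer) for n, a in cfg.afferents.items()]
    for idx, (name, count, layer) in enumerate(pops):
        z0, z1 = geo.layer_bounds(layer)
        pts = lattice_positions(count, 0.0, geo.longitudinal_um,
                                0.0, geo.transverse_um, z0, z1)
        blocks.append(pts)
        codes.append(np.full(count, idx, dtype=np.int32))
        names.append(name)
        slices[name] = slice(start, start + count)
        start += count
    return CellPositions(np.vstack(blocks) if blocks else np.empty((0, 3)),
                         np.concatenate(codes) if codes else np.empty(0, np.int32),
                         names, slices)


# ---------------------------------------------------------------------------
# Connection sampling
# ---------------------------------------------------------------------------

def bin_quotas(profile: AxonalProfile, target_n: int) -> np.ndarray:
    """Split ``target_n`` connections into radial bins by Gaussian mass,
    rounded by largest remainder so the quotas sum exactly to the target."""
    edges = np.arange(0.0, profile.extent_um + profile.bin_um, profile.bin_um)
    edges[-1] = profile.extent_um
    mass = norm.cdf(edges[1:], profile.mean_um, profile.sd_um) - \
        norm.cdf(edges[:-1], profile.mean_um, profile.sd_um)
    total = mass.sum()
    if total <= 0:
        mass = np.ones_like(mass)
        total = mass.sum()
    ideal = mass / total * target_n
    quota = np.floor(ideal).astype(np.int64)
    rem = target_n - quota.sum()
    if rem > 0:
        order = np.argsort(-(ideal - quota))
        quota[order[:rem]] += 1
    return quota


def _redistribute(quota: np.ndarray, avail: np.ndarray) -> np.ndarray:
    """Take per bin = min(quota, avail); reassign deficits to the nearest
    bins with spare candidates, alternating inward/outward."""
    take = np.minimum(quota, avail)
    deficit = int((quota - take).sum())
    nbins = quota.size
    for k in np.nonzero(quota > avail)[0]:
        need = int(quota[k] - avail[k])
        r = 1
        while need > 0 and r < nbins:
            for j in (k - r, k + r):
                if 0 <= j < nbins and need > 0:
                    spare = int(avail[j] - take[j])
                    if spare > 0:
                        add = min(spare, need)
                        take[j] += add
                        need -= add
            r += 1
    assert (take <= avail).all()
    del deficit
    return take


def sample_connections(pre_xy: np.ndarray, post_xy: np.ndarray,
                       profile: AxonalProfile, target_n_connections: int,
                       rng: np.random.Generator,
                       same_population: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three-step distance-binned sampler.

    Returns (pre_index, post_index, distance) arrays of the selected
    connections, indices local to the two position arrays.  With
    ``same_population`` self-pairs are excluded.
    """
    if target_n_connections <= 0 or len(pre_xy) == 0 or len(post_xy) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0)
    nbins = int(np.ceil(profile.extent_um / profile.bin_um))
    quota = bin_quotas(profile, int(target_n_connections))

    # step 1+3a: bin all candidate pairs within the axonal extent, in blocks
    n_pre, n_post = len(pre_xy), len(post_xy)
    cand_pairs: list[list[np.ndarray]] = [[] for _ in range(nbins)]
    cand_dist: list[list[np.ndarray]] = [[] for _ in range(nbins)]
    rows_per_block = max(1, _PAIR_CHUNK // max(n_post, 1))
    for i0 in range(0, n_pre, rows_per_block):
        i1 = min(i0 + rows_per_block, n_pre)
        d = np.sqrt(((pre_xy[i0:i1, None, :2] - post_xy[None, :, :2]) ** 2).sum(-1))
        if same_population:
            ii = np.arange(i0, i1)
            inside = ii[ii < n_post]
            d[inside - i0, inside] = np.inf
        mask = d < profile.extent_um
        pre_i, post_i = np.nonzero(mask)
        dist = d[pre_i, post_i]
        b = np.minimum((dist / profile.bin_um).astype(np.int64), nbins - 1)
        enc = (pre_i + i0).astype(np.int64) * n_post + post_i
        for k in range(nbins):
            sel = b == k
            if sel.any():
                cand_pairs[k].append(enc[sel])
                cand_dist[k].append(dist[sel])

    avail = np.array([sum(a.size for a in c) for c in cand_pairs], dtype=np.int64)
    take = _redistribute(quota, avail)

    out_enc, out_dist = [], []
    for k in range(nbins):
        if take[k] == 0 or not cand_pairs[k]:
            continue
        enc = np.concatenate(cand_pairs[k])
        dist = np.concatenate(cand_dist[k])
        if take[k] >= enc.size:
            sel = np.arange(enc.size)
        else:
            sel = rng.choice(enc.size, size=int(take[k]), replace=False)
        out_enc.append(enc[sel])
        out_dist.append(dist[sel])
    if not out_enc:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0)
    enc = np.concatenate(out_enc)
    dist = np.concatenate(out_dist)
    return enc // n_post, enc % n_post, dist


def assign_compartment_zone(cfg: NetworkConfig, pre_type: str, post_type: str,
                            rng: np.random.Generator, size: int | None = None):
    """Synapse zone(s) drawn uniformly from the pair's allowed-zone set."""
    key = (pre_type, post_type)
    if key not in cfg.budgets:
        raise KeyError(f"undeclared pair ({pre_type}, {post_type})")
    zones = cfg.budgets[key].zones
    if size is None:
        return zones[rng.integers(len(zones))]
    return np.asarray(zones, dtype=object)[rng.integers(len(zones), size=size)]


def projection_divergence(cfg: NetworkConfig, pre: str, post: str) -> int:
    """Configured connections per presynaptic cell for one projection."""
    proj = cfg.budgets[(pre, post)]
    n_pre = cfg.population_count(pre)
    if n_pre == 0 or proj.synapses == 0:
        return 0
    return int(round(proj.synapses / (proj.syn_per_conn * n_pre)))


def target_connections(cfg: NetworkConfig, pre: str, post: str) -> int:
    """Total connection count implied by the synapse budget."""
    proj = cfg.budgets[(pre, post)]
    return int(round(proj.synapses / proj.syn_per_conn))


def _rng_stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG stream (stable across runs and platforms)."""
    import zlib
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def build_edges(cfg: NetworkConfig, positions: CellPositions, pre: str, post: str,
                seed: int) -> EdgeList:
    """Generate the edge list of one projection with its own RNG stream."""
    proj = cfg.budgets[(pre, post)]
    rng = _rng_stream(seed, f"conn:{pre}->{post}")
    target = target_connections(cfg, pre, post)
    pre_i, post_i, dist = sample_connections(
        positions.of_type(pre), positions.of_type(post), cfg.profiles[pre],
        target, rng, same_population=(pre == post))
    n = pre_i.size
    if n == 0:
        return EdgeList.empty()
    zones = assign_compartment_zone(cfg, pre, post, rng, size=n)
    weight = np.full(n, proj.weight_ns * proj.syn_per_conn)
    delay = cfg.delay_offset_ms + dist / cfg.conduction_velocity_um_per_ms
    return EdgeList(
        pre_gid=positions.gids_of(pre)[pre_i],
        post_gid=positions.gids_of(post)[post_i],
        n_syn=np.full(n, proj.syn_per_conn, dtype=np.int32),
        dist_um=dist, zone=zones, weight=weight, delay_ms=delay,
        pair_labels=np.full(n, f"{pre}->{post}", dtype=object),
    )


def build_circuit(cfg: NetworkConfig, seed: int | None = None
                  ) -> tuple[CellPositions, EdgeList]:
    """Place all cells and generate every projection's edges.

    Each (pre, post) projection uses an independent named RNG stream, so
    perturbing or muting one projection leaves all others byte-identical.
    """
    seed = cfg.seed if seed is None else seed
    positions = place_cells(cfg)
    parts = [build_edges(cfg, positions, pre, post, seed)
             for (pre, post) in cfg.budgets.pairs()]
    return positions, EdgeList.concat(parts)


# ---------------------------------------------------------------------------
# Synapse census
# ---------------------------------------------------------------------------

def synapse_census(cfg: NetworkConfig, edges: EdgeList | None = None) -> pd.DataFrame:
    """Per (pre, post) synapse counts.

    In expectation mode (no edge list) the count is N_pre * divergence *
    synapses_per_connection; with an instantiated edge list it is the sum of
    n_syn over that projection's edges.
    """
    pairs = cfg.budgets.pairs()
    pres = sorted({p for p, _ in pairs})
    posts = sorted({q for _, q in pairs})
    mat = pd.DataFrame(0.0, index=pres, columns=posts)
    if edges is None:
        for pre, post in pairs:
            n_pre = cfg.population_count(pre)
            spc = cfg.budgets[(pre, post)].syn_per_conn
            mat.loc[pre, post] = n_pre * projection_divergence(cfg, pre, post) * spc
    elif len(edges):
        df = pd.DataFrame({"label": edges.pair_labels, "n_syn": edges.n_syn})
        sums = df.groupby("label")["n_syn"].sum()
        for label, s in sums.items():
            pre, post = label.split("->")
            if pre in mat.index and post in mat.columns:
                mat.loc[pre, post] = float(s)
    return mat


def census_summary(cfg: NetworkConfig) -> dict[str, int]:
    rep = census(cfg)
    out = {"total_cells": rep.total, "principal_cells": rep.principal,
           "interneurons": rep.interneurons, "afferent_units": rep.afferent_units}
    out.update({f"n_{k}": v for k, v in rep.per_type.items()})
    return out
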