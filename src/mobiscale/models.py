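"""Agent-based mobility simulators.

Five reference models whose displacement series are analyzed with exactly
the same tools as empirical data, to interpret observed displacement
correlations:

* **Lévy flight** — independent power-law move lengths, uniform headings;
  no correlation between successive displacements by construction.
* **CTRW** — a Lévy flight with independent power-law waiting times; still
  no displacement correlation, and no wait–displacement correlation.
* **EPR** (exploration / preferential return) — explore a new location
  with probability ρ·S^(−γ) (S = number of distinct known locations),
  otherwise return to a known location with probability proportional to
  its visit count.  Returns retrace earlier jumps, which correlates
  *successive* displacements but not distant ones.
* **SLAW** — least-action walk on a self-similar waypoint landscape: the
  next waypoint is chosen with probability ∝ 1/d^β among waypoints not yet
  visited in the current sweep.  The landscape is a recursive
  multiplicative cascade whose evenness rises with its Hurst parameter H;
  lower H gives a more strongly multi-scale point set and stronger
  short-range displacement correlation.
* **HTS** (hierarchical traffic system) — a weight-biased random walk on a
  layered nearest-neighbor tree embedded in the plane.  Long hops exist
  only between high-layer hubs, so displacement magnitudes change
  gradually, producing positive, slowly decaying correlations.

All simulators are deterministic given their config (seed included) and
return a :class:`~mobiscale.series.DisplacementSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import DisplacementSeries

__all__ = ["LevyConfig", "CTRWConfig", "EPRConfig", "SLAWConfig", "HTSConfig",
           "simulate_levy", "simulate_ctrw", "simulate_epr", "simulate_slaw",
           "simulate_hts", "hts_network"]


def _pareto(rng: np.random.Generator, n: int, alpha: float,
            x_min: float) -> np.ndarray:
    """Draws from p(x) ∝ x^(−alpha), x ≥ x_min (density exponent alpha > 1)."""
    return x_min * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevyConfig:
    n_steps: int = 2000
    tail_exponent: float = 2.0   # density exponent of move lengths
    x_min: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tail_exponent <= 1:
            raise ValueError("tail_exponent must exceed 1")


def simulate_levy(cfg: LevyConfig) -> DisplacementSeries:
    """Pure Lévy flight: iid Pareto move lengths, uniform headings."""
    rng = np.random.default_rng(cfg.seed)
    lengths = _pareto(rng, cfg.n_steps, cfg.tail_exponent, cfg.x_min)
    rng.random(cfg.n_steps)  # headings drawn for parity; positions unused here
    return DisplacementSeries.from_displacements(lengths, user_id="levy")


@dataclass(frozen=True)
class CTRWConfig:
    n_steps: int = 2000
    tail_exponent: float = 2.0
    x_min: float = 1.0
    wait_exponent: float = 1.8  # density exponent of waiting times
    wait_min: float = 1.0
    seed: int = 0


def simulate_ctrw(cfg: CTRWConfig) -> DisplacementSeries:
    """Continuous-time random walk: independent heavy-tailed waits and jumps."""
    rng = np.random.default_rng(cfg.seed)
    lengths = _pareto(rng, cfg.n_steps, cfg.tail_exponent, cfg.x_min)
    waits = _pareto(rng, cfg.n_steps, cfg.wait_exponent, cfg.wait_min)
    return DisplacementSeries.from_displacements(lengths, user_id="ctrw",
                                                 staytimes=waits)


@dataclass(frozen=True)
class EPRConfig:
    n_steps: int = 2000
    rho: float = 0.6             # exploration scale
    gamma: float = 0.21          # exploration exponent
    tail_exponent: float = 2.0   # density exponent of exploration jumps
    x_min: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def simulate_epr(cfg: EPRConfig, return_locations: bool = False):
    """Exploration / preferential-return walk.

    At each step a new location is explored with probability ρ·S^(−γ)
    (Pareto jump length, uniform heading from the current position);
    otherwise the agent returns to an already-known location, chosen with
    probability proportional to its visit count (the current location is
    excluded so every step is an actual movement).

    With ``return_locations`` the distinct-location count S(t) after each
    step is returned alongside the series.
    """
    rng = np.random.default_rng(cfg.seed)
    s_t = np.empty(cfg.n_steps, dtype=int)
    xs = [0.0]
    ys = [0.0]
    visits = [1]
    current = 0
    disp = np.empty(cfg.n_steps)
    for t in range(cfg.n_steps):
        s = len(xs)
        if s == 1 or rng.random() < cfg.rho * s ** (-cfg.gamma):
            L = _pareto(rng, 1, cfg.tail_exponent, cfg.x_min)[0]
            th = rng.random() * 2 * np.pi
            nx = xs[current] + L * np.cos(th)
            ny = ys[current] + L * np.sin(th)
            xs.append(nx)
            ys.append(ny)
            visits.append(0)
            nxt = s
        else:
            w = np.asarray(visits, dtype=float)
            w[current] = 0.0
            w /= w.sum()
            nxt = int(rng.choice(s, p=w))
        disp[t] = np.hypot(xs[nxt] - xs[current], ys[nxt] - ys[current])
        visits[nxt] += 1
        current = nxt
        s_t[t] = len(xs)
    series = DisplacementSeries.from_displacements(disp, user_id="epr")
    return (series, s_t) if return_locations else series


# ---------------------------------------------------------------------------
# SLAW


@dataclass(frozen=True)
class SLAWConfig:
    n_waypoints: int = 2000
    hurst: float = 0.75          # landscape self-similarity parameter
    beta: float = 1.0            # inverse-distance selection exponent
    n_steps: int = 2000
    area_side: float = 1000.0
    cascade_depth: int = 12      # levels of the recursive subdivision
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.hurst < 1):
            raise ValueError("hurst must be in (0, 1)")


def _cascade_waypoints(rng: np.random.Generator, n: int, hurst: float,
                       depth: int, side: float) -> np.ndarray:
    """Self-similar waypoint set via a recursive multiplicative cascade.

    Each cell splits into four quadrants whose mass fractions are
    Dirichlet(a, a, a, a) with concentration a = H/(1−H): H → 1 gives an
    even (near-uniform) partition, lower H a strongly clustered,
    multi-scale one.  Waypoints descend the tree independently and land
    uniformly in their terminal cell.
    """
    a = hurst / (1.0 - hurst)
    probs: dict[tuple, np.ndarray] = {}
    pts = np.empty((n, 2))
    for i in range(n):
        x0 = y0 = 0.0
        size = side
        path: tuple = ()
        for _ in range(depth):
            if path not in probs:
                probs[path] = rng.dirichlet([a, a, a, a])
            q = int(rng.choice(4, p=probs[path]))
            size /= 2.0
            x0 += (q % 2) * size
            y0 += (q // 2) * size
            path = path + (q,)
        pts[i] = (x0 + rng.random() * size, y0 + rng.random() * size)
    return pts


def simulate_slaw(cfg: SLAWConfig) -> DisplacementSeries:
    """Least-action walk on a self-similar waypoint landscape.

    The walker moves to a waypoint not yet visited in the current sweep
    with probability ∝ 1/d^β; when every waypoint has been visited the
    sweep resets.  No per-trip waypoint subsets are used — a single
    continuous walk.
    """
    rng = np.random.default_rng(cfg.seed)
    pts = _cascade_waypoints(rng, cfg.n_waypoints, cfg.hurst,
                             cfg.cascade_depth, cfg.area_side)
    n = cfg.n_waypoints
    visited = np.zeros(n, dtype=bool)
    current = int(rng.integers(n))
    visited[current] = True
    disp = np.empty(cfg.n_steps)
    for t in range(cfg.n_steps):
        if visited.all():
            visited[:] = False
            visited[current] = True
        d = np.hypot(pts[:, 0] - pts[current, 0], pts[:, 1] - pts[current, 1])
        w = np.where(visited, 0.0, 1.0 / np.maximum(d, 1e-12) ** cfg.beta)
        w /= w.sum()
        nxt = int(rng.choice(n, p=w))
        disp[t] = d[nxt]
        visited[nxt] = True
        current = nxt
    return DisplacementSeries.from_displacements(disp, user_id="slaw")


# ---------------------------------------------------------------------------
# HTS


@dataclass(frozen=True)
class HTSConfig:
    layer_sizes: tuple = (2, 8, 32, 128)  # top to bottom
    weight_base: float = 3.3              # A; layer-l weight A^(L−l)
    n_steps: int = 10_000
    area_side: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.weight_base <= 1:
            raise ValueError("weight_base A must exceed 1")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")


def hts_network(cfg: HTSConfig):
    """Build the layered nearest-neighbor tree of the HTS model.

    Nodes of every layer are placed uniformly on the square; each node
    below the top layer links to its nearest node in the layer above, and
    top-layer nodes are mutually connected.  A node in layer l (1-based
    from the top, L layers total) has weight A^(L−l).

    Returns (positions, layer_index, adjacency list, node weights).
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(cfg.layer_sizes)
    pos_list, layer_list = [], []
    for l, size in enumerate(cfg.layer_sizes):
        pos_list.append(rng.random((size, 2)) * cfg.area_side)
        layer_list.append(np.full(size, l))
    pos = np.vstack(pos_list)
    layer = np.concatenate(layer_list)
    n = pos.shape[0]
    adj: list[set] = [set() for _ in range(n)]
    offsets = np.cumsum([0] + list(cfg.layer_sizes))
    # top layer: complete graph
    for i in range(offsets[0], offsets[1]):
        for j in range(offsets[0], offsets[1]):
            if i != j:
                adj[i].add(j)
    for l in range(1, L):
        up = slice(offsets[l - 1], offsets[l])
        here = slice(offsets[l], offsets[l + 1])
        up_pos = pos[up]
        for i in range(here.start, here.stop):
            d = np.hypot(up_pos[:, 0] - pos[i, 0], up_pos[:, 1] - pos[i, 1])
            j = up.start + int(np.argmin(d))
            adj[i].add(j)
            adj[j].add(i)
    weights = cfg.weight_base ** (L - 1 - layer).astype(float)
    return pos, layer, [sorted(s) for s in adj], weights


def simulate_hts(cfg: HTSConfig) -> DisplacementSeries:
    """Weight-biased random walk on the HTS network.

    At each step the walker moves to a network neighbor with probability
    proportional to the neighbor's layer weight; the displacement is the
    planar distance between the two nodes.  The walker never jumps more
    than one edge per step, so long displacements occur only on hub–hub
    edges.
    """
    pos, layer, adj, weights = hts_network(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # walk stream, network above
    current = int(rng.integers(len(adj)))
    disp = np.empty(cfg.n_steps)
    for t in range(cfg.n_steps):
        nbrs = adj[current]
        w = weights[nbrs]
        nxt = nbrs[int(rng.choice(len(nbrs), p=w / w.sum()))]
        disp[t] = float(np.hypot(*(pos[nxt] - pos[current])))
        current = nxt
    return DisplacementSeries.from_displacements(disp, user_id="hts")
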