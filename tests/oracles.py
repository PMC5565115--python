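"""Independent brute-force oracles used to validate the encounter model.

These deliberately avoid the package's analytic formulas: relative speed
is estimated by direct Monte-Carlo over random headings, the encounter
rate by counting threshold-distance crossings of moving points in a
periodic box, and end-to-end mortality by a discrete-event simulation of
individual whales and ship transits with Bernoulli thinning.
"""

from __future__ import annotations

import numpy as np


def mc_mean_relative_speed(v_m: float, v_b: float, n: int, rng: np.random.Generator):
    """Mean |v1 - v2| over independent uniform headings; returns (mean, sem)."""
    a = rng.uniform(0.0, 2.0 * np.pi, size=n)
    b = rng.uniform(0.0, 2.0 * np.pi, size=n)
    dx = v_m * np.cos(a) - v_b * np.cos(b)
    dy = v_m * np.sin(a) - v_b * np.sin(b)
    speeds = np.hypot(dx, dy)
    return float(speeds.mean()), float(speeds.std(ddof=1) / np.sqrt(n))


def periodic_box_encounter_rate(
    r_c: float,
    box_side: float,
    v_m: float,
    v_b: float,
    n_pairs: int,
    t_total: float,
    rng: np.random.Generator,
    dt: float | None = None,
):
    """Entries into the r_c disc per pair-second for moving point pairs.

    One whale and one ship per replicate pair, independent uniform
    headings, straight-line motion with minimum-image wrapping in a
    periodic square of side ``box_side``. Counts down-crossings of the
    pair distance through r_c. Returns (rate, sem).
    """
    if dt is None:
        dt = r_c / (4.0 * max(v_m + v_b, 1e-9))
    n_steps = int(t_total / dt)
    a = rng.uniform(0, 2 * np.pi, size=n_pairs)
    b = rng.uniform(0, 2 * np.pi, size=n_pairs)
    vrel = np.column_stack([
        v_m * np.cos(a) - v_b * np.cos(b),
        v_m * np.sin(a) - v_b * np.sin(b),
    ])
    rel = rng.uniform(0, box_side, size=(n_pairs, 2))
    events = np.zeros(n_pairs)

    def min_image_dist(r):
        w = (r + box_side / 2.0) % box_side - box_side / 2.0
        return np.hypot(w[:, 0], w[:, 1])

    prev_inside = min_image_dist(rel) < r_c
    for _ in range(n_steps):
        rel = rel + vrel * dt
        inside = min_image_dist(rel) < r_c
        events += inside & ~prev_inside
        prev_inside = inside
    rates = events / (n_steps * dt)
    return float(rates.mean()), float(rates.std(ddof=1) / np.sqrt(n_pairs))


def closest_approach_encounters(ship_start, ship_dir, ship_speed, transit_time,
                                whale_pos, whale_vel, r_c):
    """Boolean per whale: pair distance dips below r_c during the transit.

    Both movers travel straight, so the squared separation is a convex
    quadratic in t and the minimum over [0, T] is exact.
    """
    rel0 = whale_pos - ship_start[None, :]
    relv = whale_vel - (ship_dir * ship_speed)[None, :]
    a = np.einsum("ij,ij->i", relv, relv)
    b = 2.0 * np.einsum("ij,ij->i", rel0, relv)
    c = np.einsum("ij,ij->i", rel0, rel0)
    t_star = np.where(a > 0, np.clip(-b / (2.0 * np.maximum(a, 1e-300)), 0.0, transit_time), 0.0)
    d2 = a * t_star**2 + b * t_star + c
    return d2 < r_c**2


def discrete_event_mortality(
    lane_start: np.ndarray,
    lane_end: np.ndarray,
    ship_speed_ms: float,
    n_voyages: int,
    hotspot_center: np.ndarray,
    hotspot_sd_m: float,
    total_whales: float,
    whale_speed_ms: float,
    r_c: float,
    p_strike_depth: float,
    p_avoid: float,
    p_lethal: float,
    rng: np.random.Generator,
):
    """Simulated strike deaths for ship transits through a Gaussian hotspot.

    Per voyage: whales ~ Poisson(total) at Gaussian positions with random
    headings; encounters detected by exact closest-approach; each
    encounter thinned by independent Bernoulli depth/avoidance/lethality
    draws. Returns (deaths, encounters).
    """
    seg = lane_end - lane_start
    seg_len = float(np.hypot(*seg))
    ship_dir = seg / seg_len
    transit_time = seg_len / ship_speed_ms
    deaths = 0
    encounters = 0
    for _ in range(n_voyages):
        k = rng.poisson(total_whales)
        if k == 0:
            continue
        pos = rng.normal(loc=hotspot_center, scale=hotspot_sd_m, size=(k, 2))
        theta = rng.uniform(0, 2 * np.pi, size=k)
        vel = whale_speed_ms * np.column_stack([np.cos(theta), np.sin(theta)])
        hit = closest_approach_encounters(lane_start, ship_dir, ship_speed_ms,
                                          transit_time, pos, vel, r_c)
        n_hit = int(hit.sum())
        encounters += n_hit
        if n_hit:
            u = rng.random(size=(n_hit, 3))
            deaths += int(((u[:, 0] < p_strike_depth)
                           & (u[:, 1] >= p_avoid)
                           & (u[:, 2] < p_lethal)).sum())
    return deaths, encounters
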