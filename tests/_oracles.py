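"""Independent simulation oracle for the ambush encounter kernel.

A motionless perceiver of radius R sits at the centre of a periodic box
filled with point prey at density N moving in straight lines at speed x
with isotropic headings.  The expected rate at which prey enter the
perception sphere is the one-way flux through it, pi R^2 N x per unit time,
which is exactly the calm-water kernel for a stationary predator.  This
module counts entry events geometrically (segment/sphere intersection, so
no tunnelling at finite time steps) and never calls the kernel under test.

Headings are redrawn at long intervals; this leaves the isotropic flux
unchanged while decorrelating successive crossings, so the event count is
near-Poisson and the Monte-Carlo error is ~1/sqrt(events).
"""

from __future__ import annotations

import numpy as np


def simulate_ambush_encounters(
    radius: float,
    prey_density: float,
    prey_speed: float,
    box_size: float = 1.0,
    total_time: float = 300.0,
    dt: float = 0.1,
    tumble_every: int = 100,
    seed: int | None = None,
) -> dict:
    """Count prey entries into a stationary perception sphere.

    Returns a dict with the empirical rate (events per unit time), the
    event count and the number of segment crossing checks performed.
    """
    rng = np.random.default_rng(seed)
    n_prey = int(round(prey_density * box_size**3))
    centre = np.full(3, box_size / 2.0)

    def isotropic(n):
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    pos = rng.uniform(0.0, box_size, size=(n_prey, 3))
    head = isotropic(n_prey)
    step_len = prey_speed * dt
    n_steps = int(round(total_time / dt))
    events = 0
    checks = 0
    # was the prey outside the sphere at the start of the step?
    rel = (pos - centre + box_size / 2.0) % box_size - box_size / 2.0
    outside = np.einsum("ij,ij->i", rel, rel) > radius**2
    for step in range(n_steps):
        if tumble_every and step and step % tumble_every == 0:
            head = isotropic(n_prey)
        start = (pos - centre + box_size / 2.0) % box_size - box_size / 2.0  # min image
        delta = head * step_len
        # closest approach of the segment start -> start+delta to the origin
        t = np.clip(-np.einsum("ij,ij->i", start, delta) / (step_len**2), 0.0, 1.0)
        closest = start + t[:, None] * delta
        d2 = np.einsum("ij,ij->i", closest, closest)
        hit = d2 <= radius**2
        events += int(np.count_nonzero(outside & hit))
        checks += n_prey
        pos = (pos + delta) % box_size
        end = start + delta
        outside = np.einsum("ij,ij->i", end, end) > radius**2
    return {
        "rate": events / total_time,
        "events": events,
        "checks": checks,
        "expected_rate": np.pi * radius**2 * prey_density * prey_speed,
    }
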