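"""Independent reference simulator used as a test oracle.

Deliberately written the straightforward way: one trial at a time, inputs
held as mutable state and advanced by per-step linear increments
(input += k * RoR * dt), the field stepped with an explicit Euler update.
It shares no code with the package engine beyond the parameter values, so
agreement between the two is a meaningful check of the vectorized
closed-form implementation.
"""

from __future__ import annotations

import numpy as np

# baseline constants (duplicated on purpose; the oracle must not import the
# package's closed-form machinery)
N = 100
DX = 0.1
DT = 1.0
TAU = 4.0
BETA = 0.09
THRESHOLD = 0.7
RESTING = -30.0
SIGMA = 0.85
SF = 74.7
SHIFT = 0.8
GAMMA = 0.6
AMP = 1.05
EXCLUSION = 1.0

T_START = -1000.0
T_FIX_OFF = -200.0
T_STIM = 0.0
T_END = 600.0

LEVEL_TABLE = {
    "shared_onset_delay": (140.0, 155.0, 170.0),
    "automated_motor_ror": (0.04, 0.06, 0.08),
    "automated_motor_max": (4.0, 6.0, 8.0),
    "voluntary_motor_ror": (0.05, 0.10, 0.15),
    "voluntary_fixation_max": (4.0, 6.0, 8.0),
    "voluntary_preparation_max": (4.0, 6.0, 8.0),
    "inhibitory_gate_ror": (0.05, 0.10, 0.15),
    "inhibitory_gate_max": (4.0, 6.0, 8.0),
    "peripheral_inhibition_ror": (0.05, 0.10, 0.15),
    "peripheral_inhibition_max": (4.0, 6.0, 8.0),
}
LEVEL_INDEX = {"small": 0, "medium": 1, "large": 2}


def positions():
    return np.arange(1, N + 1) * DX - 5.0


def profile(mu):
    x = positions()
    d = np.abs(x - mu)
    d = np.minimum(d, 10.0 - d)
    return AMP * np.exp(-d * d / (2.0 * GAMMA * GAMMA))


def weight_matrix():
    w = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            k = abs(i - j)
            d = min(k, N - k) * DX
            w[i, j] = SF * np.exp(-d * d / (2.0 * SIGMA * SIGMA))
    return (w - SHIFT * SF) * DX


def simulate_reference(task, levels, stimulus_side="right",
                       ablations=frozenset(), crosstalk=False, fraction=0.25,
                       record_u=False):
    """Simulate one trial by per-step accumulation.

    ``levels``: mapping attribute -> small|medium|large.
    Returns dict with srt (or None), node, direction, and optionally the
    stacked u trajectory.
    """
    val = {a: LEVEL_TABLE[a][LEVEL_INDEX[levels[a]]] for a in LEVEL_TABLE}
    stim_x = 2.5 if stimulus_side == "right" else -2.5
    goal_x = stim_x if task == "pro" else -stim_x
    delay = val["shared_onset_delay"]

    k_stim = profile(stim_x)
    k_goal = profile(goal_x)
    k_center = profile(0.0)
    k_prep = np.maximum(profile(-2.5), profile(2.5))
    notch = 1.0 - k_center / AMP

    def ror(name, v):
        return 0.0 if name in ablations else v

    vis_ror = ror("visual_transient", 0.15)
    vis_cap_vec = (8.0 / AMP) * k_stim
    vis_rise_ms = (max(50.0, np.ceil((8.0 / AMP) / vis_ror / DT) * DT)
                   if vis_ror > 0 else np.inf)
    am_ror = ror("automated_motor", val["automated_motor_ror"])
    am_cap_vec = (val["automated_motor_max"] / AMP) * k_stim
    af_ror = ror("automated_fixation", 0.10)
    vm_ror = ror("voluntary_motor", val["voluntary_motor_ror"])
    vf_ror = ror("voluntary_fixation", 0.10)
    vf_cap = val["voluntary_fixation_max"] / AMP
    vp_max = val["voluntary_preparation_max"]
    vp_ramp = (T_STIM - T_START) - delay
    vp_ror = 0.0 if "voluntary_preparation" in ablations else \
        vp_max / (AMP * vp_ramp)
    g_ror = ror("inhibitory_gate", val["inhibitory_gate_ror"])
    g_max = val["inhibitory_gate_max"]
    p_ror = ror("peripheral_inhibition", val["peripheral_inhibition_ror"])
    p_max = val["peripheral_inhibition_max"]

    # mutable input state
    vis = np.zeros(N)
    am = np.zeros(N)
    af = (6.0 / AMP) * k_center
    vm = np.zeros(N)
    vf = vf_cap * k_center
    vp = np.zeros(N)
    gate = np.full(N, -g_max)
    periph = -p_max * notch

    w = weight_matrix()
    u = np.full(N, RESTING)
    a = 1.0 / (1.0 + np.exp(-BETA * u))
    x = positions()
    mirror = (N - 2 - np.arange(N)) % N
    elig = np.abs(x) > EXCLUSION

    traj = []
    n_steps = int(round((T_END - T_START) / DT))
    for s in range(1, n_steps + 1):
        t = T_START + s * DT

        # per-step input accumulation
        if t > T_STIM + 50.0:
            if t <= T_STIM + 50.0 + vis_rise_ms:
                vis = np.minimum(vis + k_stim * vis_ror * DT, vis_cap_vec)
            else:
                vis = np.maximum(vis - k_stim * (vis_ror / 2.0) * DT, 0.0)
        if t > T_STIM + 60.0:
            am = np.minimum(am + k_stim * am_ror * DT, am_cap_vec)
        if t > T_FIX_OFF + 60.0:
            af = np.maximum(af - k_center * af_ror * DT, 0.0)
        if t > T_STIM + delay:
            vm = vm + k_goal * vm_ror * DT
            vf = np.maximum(vf - k_center * vf_ror * DT, 0.0)
            gate = np.minimum(gate + k_goal * g_ror * DT, 0.0)
            periph = np.minimum(periph + AMP * p_ror * DT, 0.0)
        if T_START + delay < t <= T_STIM:
            vp = np.minimum(vp + k_prep * vp_ror * DT, (vp_max / AMP) * k_prep)

        am_eff = am
        if crosstalk:
            am_eff = np.maximum(am - fraction * vm[mirror], 0.0)
        c_ext = vis + am_eff + af + vm + vf + vp + gate + periph

        c_int = w @ a
        u = (1.0 - DT / TAU) * u + (DT / TAU) * (c_ext + c_int)
        a = 1.0 / (1.0 + np.exp(-BETA * u))
        if record_u:
            traj.append(u.copy())

        masked = np.where(elig, a, -np.inf)
        if masked.max() >= THRESHOLD:
            cand = np.flatnonzero(masked == masked.max())
            absx = np.abs(x[cand])
            cand = cand[absx == absx.min()]
            node = int(cand[np.argmin(x[cand])])
            return {"srt": t, "node": node,
                    "direction": "right" if x[node] > 0 else "left",
                    "u": np.array(traj) if record_u else None}
    return {"srt": None, "node": None, "direction": "none",
            "u": np.array(traj) if record_u else None}
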