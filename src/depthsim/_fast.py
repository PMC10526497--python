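"""Scalar fast path for the trial inner loop.

`FastAgent` implements exactly the same one-step update as
:meth:`depthsim.agent.DepthAgent.step` (instantaneous-error mode) using plain
Python floats, which is ~5x faster than the array-based reference for these
tiny state vectors.  A regression test pins the two implementations against
each other step by step; any change to the reference must be mirrored here.
"""

from __future__ import annotations

from math import cos, exp, isfinite, sin, sqrt, tan


import numpy as np

from .agent import AgentConfig, Phase, BlockMechanism
from .inference import DivergenceError


class FastAgent:
    """Flat-state replica of ``DepthAgent`` (instantaneous errors only)."""

    __slots__ = (
        "cfg", "ax", "ay", "axp", "ayp", "tha", "thv", "thap", "thvp",
        "rx", "ry", "rxp", "ryp", "c", "cp", "aa", "av", "free_energy",
    )

    def __init__(self, cfg: AgentConfig, init_position, init_angles) -> None:
        if not cfg.instantaneous_errors:
            raise ValueError("FastAgent supports instantaneous_errors only")
        self.cfg = cfg
        self.ax, self.ay = float(init_position[0]), float(init_position[1])
        self.axp = self.ayp = 0.0
        self.tha, self.thv = float(init_angles[0]), float(init_angles[1])
        self.thap = self.thvp = 0.0
        self.rx, self.ry = [0.0, 0.0], [0.0, 0.0]
        self.rxp, self.ryp = [0.0, 0.0], [0.0, 0.0]
        self.c, self.cp = [0.0, 0.0], [0.0, 0.0]
        L, f = cfg.L, cfg.focal
        for i, (l, s_th) in enumerate(((L, self.tha - self.thv), (-L, self.tha + self.thv))):
            c_, s_ = cos(s_th), sin(s_th)
            self.rx[i] = c_ * self.ax + s_ * self.ay - l * s_
            self.ry[i] = -s_ * self.ax + c_ * self.ay - l * c_
            self.c[i] = f * self.ry[i] / self.rx[i]
        self.aa = self.av = 0.0
        self.free_energy = 0.0

    def estimate(self) -> np.ndarray:
        return np.array([self.ax, self.ay])

    def step(self, sp_a, sp_v, spp_a, spp_v, sv0, sv1, phase: Phase) -> None:
        cfg = self.cfg
        dt, L, f = cfg.dt, cfg.L, cfg.focal
        zero_pp = (
            phase is Phase.PERCEPTION
            and cfg.mechanism is BlockMechanism.ZERO_PROPRIO_PRECISION
        )
        lam = cfg.lam if (phase is not Phase.PERCEPTION or zero_pp) else 0.0
        frozen_a = phase is Phase.ACTION
        act_on = phase is not Phase.PERCEPTION

        sv = (sv0, sv1)
        up_ax = up_ay = 0.0
        up_tha = up_thv = 0.0
        F = 0.0
        new_r = [(0.0, 0.0), (0.0, 0.0)]
        new_rp = [(0.0, 0.0), (0.0, 0.0)]
        new_c = [0.0, 0.0]
        new_cp = [0.0, 0.0]
        for i in range(2):
            l = L if i == 0 else -L
            sign = -1.0 if i == 0 else 1.0
            th = self.tha + sign * self.thv
            c_, s_ = cos(th), sin(th)
            pred_rx = c_ * self.ax + s_ * self.ay - l * s_
            pred_ry = -s_ * self.ax + c_ * self.ay - l * c_
            rx, ry = self.rx[i], self.ry[i]
            pred_c = f * ry / rx
            raw_rx = rx - pred_rx
            raw_ry = ry - pred_ry
            raw_c = self.c[i] - pred_c
            raw_v = sv[i] - self.c[i]
            raw_mu_rx = self.rxp[i]
            raw_mu_ry = self.ryp[i]
            raw_mu_c = self.cp[i] + lam * self.c[i]
            F += 0.5 * (
                cfg.pi_r * (raw_rx * raw_rx + raw_ry * raw_ry)
                + cfg.pi_c * raw_c * raw_c
                + cfg.pi_v * raw_v * raw_v
                + cfg.gamma_r * (raw_mu_rx * raw_mu_rx + raw_mu_ry * raw_mu_ry)
                + cfg.gamma_c * raw_mu_c * raw_mu_c
            )
            eps_rx = cfg.pi_r * raw_rx
            eps_ry = cfg.pi_r * raw_ry
            eps_c = cfg.pi_c * raw_c
            eps_v = cfg.pi_v * raw_v
            eps_mu_c = cfg.gamma_c * raw_mu_c

            up_ax += c_ * eps_rx - s_ * eps_ry
            up_ay += s_ * eps_rx + c_ * eps_ry
            # d(pred_r)/dth = (pred_ry, -pred_rx); contract with eps_r
            g = eps_rx * pred_ry - eps_ry * pred_rx
            up_tha += g
            up_thv += sign * g
            asc_x = -f * ry / (rx * rx) * eps_c
            asc_y = f / rx * eps_c
            new_r[i] = (
                rx + dt * (self.rxp[i] + cfg.k_r * (asc_x - eps_rx)),
                ry + dt * (self.ryp[i] + cfg.k_r * (asc_y - eps_ry)),
            )
            new_rp[i] = (
                self.rxp[i] - dt * cfg.k_r * cfg.gamma_r * raw_mu_rx,
                self.ryp[i] - dt * cfg.k_r * cfg.gamma_r * raw_mu_ry,
            )
            new_c[i] = self.c[i] + dt * (
                self.cp[i] + cfg.k_c * (eps_v - eps_c - lam * eps_mu_c)
            )
            new_cp[i] = self.cp[i] - dt * cfg.k_c * eps_mu_c

        raw_pa = sp_a - self.tha
        raw_pv = sp_v - self.thv
        raw_ppa = spp_a - self.thap
        raw_ppv = spp_v - self.thvp
        raw_mu_ax, raw_mu_ay = self.axp, self.ayp
        raw_mu_tha, raw_mu_thv = self.thap, self.thvp
        F += 0.5 * (
            cfg.pi_p * (raw_pa * raw_pa + raw_pv * raw_pv)
            + cfg.pi_pp * (raw_ppa * raw_ppa + raw_ppv * raw_ppv)
            + cfg.gamma_a * (raw_mu_ax * raw_mu_ax + raw_mu_ay * raw_mu_ay)
            + cfg.gamma_theta * (raw_mu_tha * raw_mu_tha + raw_mu_thv * raw_mu_thv)
        )
        self.free_energy = F

        eps_pa = 0.0 if zero_pp else cfg.pi_p * raw_pa
        eps_pv = 0.0 if zero_pp else cfg.pi_p * raw_pv
        eps_ppa = 0.0 if zero_pp else cfg.pi_pp * raw_ppa
        eps_ppv = 0.0 if zero_pp else cfg.pi_pp * raw_ppv

        if not frozen_a:
            self.ax += dt * (self.axp + cfg.k_a * up_ax)
            self.ay += dt * (self.ayp + cfg.k_a * up_ay)
            self.axp -= dt * cfg.k_a * cfg.gamma_a * raw_mu_ax
            self.ayp -= dt * cfg.k_a * cfg.gamma_a * raw_mu_ay
        self.tha += dt * (self.thap + cfg.k_theta * (up_tha + eps_pa))
        self.thv += dt * (self.thvp + cfg.k_theta * (up_thv + eps_pv))
        self.thap -= dt * cfg.k_theta * cfg.gamma_theta * raw_mu_tha
        self.thvp -= dt * cfg.k_theta * cfg.gamma_theta * raw_mu_thv
        for i in range(2):
            self.rx[i], self.ry[i] = new_r[i]
            self.rxp[i], self.ryp[i] = new_rp[i]
            self.c[i] = new_c[i]
            self.cp[i] = new_cp[i]
        if act_on and not zero_pp:
            self.aa -= dt * cfg.k_action * (eps_pa + eps_ppa)
            self.av -= dt * cfg.k_action * (eps_pv + eps_ppv)
        if not (isfinite(self.ax) and isfinite(self.ay) and isfinite(self.tha)
                and isfinite(self.thv) and isfinite(self.rx[0]) and isfinite(self.rx[1])
                and isfinite(self.c[0]) and isfinite(self.c[1])):
            raise DivergenceError("belief update produced non-finite values")


def run_fast_trial(
    cfg: AgentConfig,
    target,
    init_position,
    init_angles,
    n_steps: int,
    cycle_length: int,
    rng: np.random.Generator,
    noise_k: float,
    nonuniform: bool,
    sigma0: float = 0.05,
    sigma_is_variance: bool = False,
    variant: str = "cycled",
    far_clip: float = 10.0,
    angle_limit: float = np.pi / 2,
):
    """Run one trial with the scalar agent; returns (errors, final_agent).

    ``variant``: "cycled" alternates perception/action phases (perception
    first), "perception" runs perception only with fixed eyes, and
    "simultaneous" keeps every pathway open at each step.
    """
    agent = FastAgent(cfg, init_position, init_angles)
    tx, ty = float(target[0]), float(target[1])
    errors = np.empty(n_steps)
    errors.fill(np.inf)
    # divergent trials overflow before the non-finite check catches them
    err_state = np.seterr(all="ignore")
    try:
        return _trial_loop(agent, errors, n_steps, cycle_length, variant, cfg,
                           tx, ty, rng, noise_k, nonuniform, sigma0,
                           sigma_is_variance, far_clip, angle_limit)
    finally:
        np.seterr(**err_state)


def _trial_loop(agent, errors, n_steps, cycle_length, variant, cfg, tx, ty,
                rng, noise_k, nonuniform, sigma0, sigma_is_variance, far_clip,
                angle_limit):
    tha, thv = agent.tha, agent.thv
    va = vv = 0.0
    L, f, dt = cfg.L, cfg.focal, cfg.dt
    lim = angle_limit - 1e-9
    for t in range(n_steps):
        if variant == "perception":
            phase = Phase.PERCEPTION
        elif variant == "simultaneous":
            phase = Phase.SIMULTANEOUS
        else:
            phase = (
                Phase.PERCEPTION if (t // cycle_length) % 2 == 0 else Phase.ACTION
            )
        try:
            # --- generative process: true projections and fovea noise
            th0, th1 = tha - thv, tha + thv
            c0_, s0_ = cos(th0), sin(th0)
            c1_, s1_ = cos(th1), sin(th1)
            r0x = c0_ * tx + s0_ * ty - L * s0_
            r0y = -s0_ * tx + c0_ * ty - L * c0_
            r1x = c1_ * tx + s1_ * ty + L * s1_
            r1y = -s1_ * tx + c1_ * ty + L * c1_
            if r0x <= 0 or r1x <= 0:
                return errors, agent, True  # target behind an eye
            sv0 = f * r0y / r0x
            sv1 = f * r1y / r1x
            if nonuniform:
                t0_, t1_ = tan(th0), tan(th1)
                denom = t1_ - t0_
                if abs(denom) < 1e-12:
                    fx, fy = far_clip * cos(tha), far_clip * sin(tha)
                else:
                    ix = 2.0 * L / denom
                    if ix <= 0:
                        fx, fy = far_clip * cos(tha), far_clip * sin(tha)
                    else:
                        fx, fy = ix, L + ix * t0_
                d = sqrt((fx - tx) ** 2 + (fy - ty) ** 2)
                sigma = exp(d / noise_k)
                if sigma_is_variance:
                    sigma = sqrt(sigma)
                sigma *= sigma0
                g = rng.standard_normal(2)
                sv0 += sigma * g[0]
                sv1 += sigma * g[1]
            agent.step(tha, thv, va, vv, sv0, sv1, phase)
        except (DivergenceError, OverflowError, ZeroDivisionError):
            return errors, agent, True
        if phase is not Phase.PERCEPTION:
            na = tha + dt * agent.aa
            nv = thv + dt * agent.av
            nth0 = min(max(na - nv, -lim), lim)
            nth1 = min(max(na + nv, -lim), lim)
            na, nv = (nth0 + nth1) / 2.0, (nth1 - nth0) / 2.0
            va, vv = (na - tha) / dt, (nv - thv) / dt
            tha, thv = na, nv
        else:
            va = vv = 0.0
        ex, ey = agent.ax - tx, agent.ay - ty
        errors[t] = sqrt(ex * ex + ey * ey)
    return errors, agent, False
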