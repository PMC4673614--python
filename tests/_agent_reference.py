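"""Literal per-agent reference implementation of the cell-cycle update.

Every tumor cell is an explicit list entry with its own site and phenotype;
fates and placements are drawn one agent at a time with independently written
formula code.  Used only as a distributional oracle against the count-based
scheduler on small lattices — deliberately naive and slow.
"""

from __future__ import annotations

import math

import numpy as np

from tumorgame.ecm import EcmParams, degrade_ecm
from tumorgame.nutrient import NutrientParams, diffusion_substep

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class AgentWorld:
    """Agents as (row, col, phenotype) with phenotype 'P', 'I' or 'N'."""

    def __init__(self, config, rng):
        self.config = config
        L = config.L
        self.rho = rng.random((L, L))
        self.phi = rng.random((L, L))
        self.phi[0, :] = self.phi[-1, :] = self.phi[:, 0] = self.phi[:, -1] = 1.0
        c = (L - 1) // 2
        self.rho[c, c] = 0.0
        self.agents = [[c, c, "P"]]

    def counts(self):
        L = self.config.L
        n_p = np.zeros((L, L), dtype=int)
        n_i = np.zeros((L, L), dtype=int)
        n_n = np.zeros((L, L), dtype=int)
        for r, c, ph in self.agents:
            if ph == "P":
                n_p[r, c] += 1
            elif ph == "I":
                n_i[r, c] += 1
            else:
                n_n[r, c] += 1
        return n_p, n_i, n_n

    def step(self, rng):
        cfg = self.config
        L = cfg.L
        n_p, n_i, n_n = self.counts()
        living = n_p + n_i
        self.rho = degrade_ecm(
            self.rho, living, EcmParams(cfg.gamma, cfg.degrade_neighbors)
        )
        params = NutrientParams(cfg.D, cfg.k, 1.0 / cfg.n_sub, cfg.consumption_form)
        for _ in range(cfg.n_sub):
            self.phi = diffusion_substep(self.phi, living, params)
        # necrosis
        for agent in self.agents:
            r, c, ph = agent
            if ph != "N" and self.phi[r, c] < cfg.phi_c:
                agent[2] = "N"
        n_p, n_i, n_n = self.counts()
        total = n_p + n_i + n_n
        phi = self.phi
        new_agents = []
        for r, c, ph in self.agents:
            if ph == "N":
                new_agents.append([r, c, "N"])
                continue
            n_t = n_p[r, c] + n_i[r, c]
            # neighborhood: own grid (minus self) plus Moore ring, last-round labels
            nb_p, nb_i = n_p[r, c], n_i[r, c]
            if ph == "P":
                nb_p -= 1
            else:
                nb_i -= 1
            for dr, dc in MOORE:
                rr, cc = r + dr, c + dc
                if 0 <= rr < L and 0 <= cc < L:
                    nb_p += n_p[rr, cc]
                    nb_i += n_i[rr, cc]
            partners = nb_p + nb_i
            dp = cfg.payoff.a_pp * nb_p + cfg.payoff.a_pi * nb_i
            di = cfg.payoff.b_ip * nb_p + cfg.payoff.b_ii * nb_i
            if cfg.payoff_aggregation == "mean" and partners > 0:
                dp /= partners
                di /= partners
            x_p = phi[r, c] / (n_t * cfg.theta_p)
            x_i = phi[r, c] / (n_t * cfg.theta_i)
            raw_p = min(max(1.0 - math.exp(-x_p * x_p) + dp, 0.0), 1.0)
            raw_i = min(max(math.exp(-x_i * x_i) + di, 0.0), 1.0)
            s = raw_p + raw_i
            if s == 0.0:
                new_agents.append([r, c, ph])  # hold
                continue
            eligible = [
                (r + dr, c + dc)
                for dr, dc in MOORE
                if 0 <= r + dr < L and 0 <= c + dc < L and self.rho[r + dr, c + dc] == 0.0
            ]
            if rng.random() < raw_p / s:
                # divide: parent stays proliferative, daughter placed
                new_agents.append([r, c, "P"])
                target = self._choose(eligible + [(r, c)], total, phi, rng)
                new_agents.append([target[0], target[1], "P"])
            else:
                if eligible:
                    target = self._choose(eligible, total, phi, rng)
                else:
                    target = (r, c)
                new_agents.append([target[0], target[1], "I"])
        self.agents = new_agents

    @staticmethod
    def _choose(candidates, total, phi, rng):
        best = None
        best_key = None
        for site in candidates:
            key = (total[site], -phi[site])
            if best_key is None or key < best_key:
                best_key, best = key, [site]
            elif key == best_key:
                best.append(site)
        return best[int(rng.integers(len(best)))]


def run_agent_reference(config, seed, n_steps):
    rng = np.random.default_rng(seed)
    world = AgentWorld(config, rng)
    for _ in range(n_steps):
        world.step(rng)
    return world
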