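"""Adaptive-moment estimation optimiser (the standard choice for this GAN family)."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for slot, arr in zip(self.m, state["m"]):
            slot[...] = arr
        for slot, arr in zip(self.v, state["v"]):
            slot[...] = arr
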