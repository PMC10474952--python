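"""Adam optimizer over the layer parameter stores."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    """Adam with either coupled (L2) or decoupled (AdamW) weight decay.

    ``decoupled=False`` adds ``weight_decay * param`` to the raw gradient
    before the moment updates (torch.optim.Adam semantics); ``decoupled=True``
    shrinks parameters multiplicatively by ``lr * weight_decay`` per step
    (torch.optim.AdamW semantics), which never drives a small-gradient
    weight through zero the way the normalized L2 term can.
    """

    def __init__(self, root: Layer, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decoupled: bool = False) -> None:
        self.root = root
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.decoupled = bool(decoupled)
        self.t = 0
        self._m: list[np.ndarray] = []
        self._v: list[np.ndarray] = []
        for lyr in root.layers():
            for k in sorted(lyr.params):
                self._m.append(np.zeros_like(lyr.params[k]))
                self._v.append(np.zeros_like(lyr.params[k]))

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        i = 0
        for lyr in self.root.layers():
            for k in sorted(lyr.params):
                g = lyr.grads[k]
                if self.weight_decay and not self.decoupled:
                    g = g + self.weight_decay * lyr.params[k]
                elif self.weight_decay:
                    lyr.params[k] *= 1.0 - self.lr * self.weight_decay
                m, v = self._m[i], self._v[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                lyr.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                i += 1
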