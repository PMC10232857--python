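"""SGD with momentum and weight decay over named parameter maps."""

from __future__ import annotations

import numpy as np


class SGD:
    """Classical momentum SGD: v <- mu*v + (g + wd*theta); theta <- theta - lr*v.

    Velocity buffers are keyed by parameter name and live with the owner
    (in federated training: the client), persisting across rounds.
    """

    def __init__(self, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        if lr < 0 or momentum < 0 or weight_decay < 0:
            raise ValueError("lr, momentum and weight_decay must be >= 0")
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        """Update `params` in place from `grads` (missing grads are skipped)."""
        for name, theta in params.items():
            if name not in grads:
                continue
            g = grads[name].astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * theta
            v = self.velocity.get(name)
            v = g if v is None else self.momentum * v + g
            self.velocity[name] = v
            theta -= self.lr * v
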