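"""Stochastic gradient descent with momentum and a plateau LR scheduler."""

from __future__ import annotations

import numpy as np

from .nn import Parameter

__all__ = ["SGD", "ReduceLROnPlateau"]


class SGD:
    """SGD with classical momentum and (optional) decoupled L2 weight decay.

    ``param_groups`` is a list of dicts with keys ``params`` (list of
    :class:`Parameter`) and optionally ``weight_decay``; the learning rate is
    shared across groups so a plateau scheduler can scale it globally.
    """

    def __init__(self, param_groups: list[dict], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.param_groups = []
        for group in param_groups:
            g = {"params": list(group["params"]),
                 "weight_decay": float(group.get("weight_decay", 0.0))}
            g["velocity"] = [np.zeros_like(p.data) for p in g["params"]]
            self.param_groups.append(g)

    def zero_grad(self) -> None:
        for g in self.param_groups:
            for p in g["params"]:
                p.zero_grad()

    def step(self) -> None:
        for g in self.param_groups:
            wd = g["weight_decay"]
            for p, v in zip(g["params"], g["velocity"]):
                if p.grad is None:
                    continue
                grad = p.grad
                if wd:
                    grad = grad + wd * p.data
                v *= self.momentum
                v += grad
                p.data -= self.lr * v


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` epochs without a new
    best monitored value (lower is better)."""

    def __init__(self, optimizer: SGD, factor: float = 0.1, patience: int = 10,
                 min_lr: float = 0.0):
        self.optimizer = optimizer
        self.factor = float(factor)
        self.patience = int(patience)
        self.min_lr = float(min_lr)
        self.best = np.inf
        self.num_bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> bool:
        """Record one epoch's monitored value; returns True if the LR dropped."""
        if metric < self.best:
            self.best = float(metric)
            self.num_bad_epochs = 0
            return False
        self.num_bad_epochs += 1
        if self.num_bad_epochs >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.num_bad_epochs = 0
            return True
        return False
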