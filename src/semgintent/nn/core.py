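"""Minimal layer/module machinery for the numpy network implementation.

Each module owns its parameters, caches whatever its backward pass needs
during ``forward``, and accumulates parameter gradients during ``backward``.
Composite networks orchestrate their children explicitly, which keeps the
data flow auditable and lets finite-difference tests check every layer in
isolation.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

DEFAULT_DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: children, parameters and buffers are discovered via
    attributes.  ``buffer_names`` lists non-trainable state (e.g. batch-norm
    running statistics) that must travel with checkpoints."""

    buffer_names: tuple[str, ...] = ()

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_modules(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{path}.{i}.")

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mpath, mod in self.named_modules(prefix):
            for name, value in vars(mod).items():
                if isinstance(value, Parameter):
                    yield f"{mpath}{name}", value

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        for mpath, mod in self.named_modules(prefix):
            for name in type(mod).buffer_names:
                yield f"{mpath}{name}", mod, name

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def n_parameters(self) -> int:
        """Count of trainable scalars (buffers/running stats excluded)."""
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for bname, mod, attr in self.named_buffers():
            state[bname] = getattr(mod, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_buffers = {bname: (mod, attr) for bname, mod, attr in self.named_buffers()}
        expected = set(own_params) | set(own_buffers)
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(
                f"state dict mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        for name, p in own_params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data[...] = state[name]
        for bname, (mod, attr) in own_buffers.items():
            setattr(mod, attr, state[bname].copy())

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


def uniform_init(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=DEFAULT_DTYPE
) -> np.ndarray:
    """Kaiming-style uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)
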