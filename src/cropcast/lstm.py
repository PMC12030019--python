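"""Gated recurrent refinement of the Informer trajectory.

A single LSTM layer runs along the predicted status trajectory and a linear
readout adds a per-step correction on top of it (residual form), so a
zero-parameter refiner is exactly the identity. Gate equations are the
standard ones: sigmoid forget/input/output gates on the concatenated
[h_{t-1}, x_t], tanh candidate state,
C_t = C_{t-1} * f_t + i_t * C~_t,  h_t = o_t * tanh(C_t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["LstmParams", "lstm_cell_step", "refine_sequence", "LstmRefiner"]


@dataclass
class LstmParams:
    """Weights for one LSTM cell; each w_* has shape
    (hidden + n_in, hidden), each b_* shape (hidden,)."""

    w_f: np.ndarray
    b_f: np.ndarray
    w_i: np.ndarray
    b_i: np.ndarray
    w_c: np.ndarray
    b_c: np.ndarray
    w_o: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[1]

    @classmethod
    def zeros(cls, n_in: int, hidden: int) -> "LstmParams":
        w = lambda: np.zeros((hidden + n_in, hidden))
        b = lambda: np.zeros(hidden)
        return cls(w(), b(), w(), b(), w(), b(), w(), b())

    def validate(self, n_in: int) -> None:
        h = self.hidden_size
        for name in ("w_f", "w_i", "w_c", "w_o"):
            if getattr(self, name).shape != (h + n_in, h):
                raise ValueError(f"{name} must have shape ({h + n_in}, {h})")
        for name in ("b_f", "b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
                   params: LstmParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step on plain arrays. ``x_t``: (n_in,), states: (hidden,)."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    params.validate(len(x_t))
    z = np.concatenate([h_prev, x_t])
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    f = sig(z @ params.w_f + params.b_f)
    i = sig(z @ params.w_i + params.b_i)
    c_tilde = np.tanh(z @ params.w_c + params.b_c)
    o = sig(z @ params.w_o + params.b_o)
    C_t = C_prev * f + i * c_tilde
    h_t = o * np.tanh(C_t)
    return h_t, C_t


class LstmRefiner:
    """Trainable residual refiner: refined_t = y_t + readout(h_t)."""

    DT = np.float32

    def __init__(self, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        n_in = 1
        scale = 1.0 / np.sqrt(hidden + n_in)
        mk = lambda: Tensor.param(
            rng.uniform(-scale, scale, size=(hidden + n_in, hidden)).astype(self.DT))
        self.w_f, self.w_i, self.w_c, self.w_o = mk(), mk(), mk(), mk()
        self.b_f = Tensor.param(np.ones(hidden, dtype=self.DT))  # forget-bias 1 convention
        self.b_i = Tensor.param(np.zeros(hidden, dtype=self.DT))
        self.b_c = Tensor.param(np.zeros(hidden, dtype=self.DT))
        self.b_o = Tensor.param(np.zeros(hidden, dtype=self.DT))
        self.w_out = Tensor.param(np.zeros((hidden, 1), dtype=self.DT))  # identity at init
        self.b_out = Tensor.param(np.zeros(1, dtype=self.DT))

    def params(self) -> dict[str, Tensor]:
        return {f"lstm.{k}": v for k, v in vars(self).items()
                if isinstance(v, Tensor)}

    def set_weights(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, v in arrays.items():
            if k not in params:
                raise KeyError(f"unknown weight {k!r}")
            params[k].data = np.asarray(v, dtype=float)

    def refine(self, traj: Tensor, warmup: np.ndarray | None = None) -> Tensor:
        """traj: (B, T) -> refined (B, T).

        ``warmup`` (B, W) is an optional observed-status tail run through the
        cell first (outputs discarded) so the recurrent state is conditioned
        on history rather than starting cold at the forecast origin.
        """
        if traj.data.dtype != self.DT:
            traj = Tensor(traj.data.astype(self.DT)) if not traj.requires_grad else traj
        B, T = traj.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=self.DT))
        C = Tensor(np.zeros((B, self.hidden), dtype=self.DT))

        def step(x_t, h, C):
            z = concat([h, x_t], axis=-1)
            f = (z @ self.w_f + self.b_f).sigmoid()
            i = (z @ self.w_i + self.b_i).sigmoid()
            c_tilde = (z @ self.w_c + self.b_c).tanh()
            o = (z @ self.w_o + self.b_o).sigmoid()
            C = C * f + i * c_tilde
            h = o * C.tanh()
            return h, C

        if warmup is not None:
            wu = np.asarray(warmup, dtype=self.DT)
            for t in range(wu.shape[1]):
                h, C = step(Tensor(wu[:, t:t + 1]), h, C)
        outs = []
        for t in range(T):
            x_t = traj[:, t:t + 1]  # (B, 1)
            h, C = step(x_t, h, C)
            outs.append(x_t + h @ self.w_out + self.b_out)
        return concat(outs, axis=-1)


def refine_sequence(trajectory: np.ndarray,
                    params: LstmParams | LstmRefiner | None = None,
                    head: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Run the refiner across a 1-D trajectory; length preserved.

    Accepts either a trained :class:`LstmRefiner` or raw :class:`LstmParams`
    plus a ``(w_out, b_out)`` readout. With all-zero parameters the result
    equals the input (residual identity).
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 1 or len(traj) == 0:
        raise ValueError("trajectory must be a non-empty 1-D vector")
    if not np.isfinite(traj).all():
        raise ValueError("trajectory must be finite")
    if isinstance(params, LstmRefiner):
        return params.refine(Tensor(traj[None])).data[0]
    if params is None:
        params = LstmParams.zeros(1, 32)
    if head is None:
        head = (np.zeros((params.hidden_size, 1)), np.zeros(1))
    w_out, b_out = head
    h = np.zeros(params.hidden_size)
    C = np.zeros(params.hidden_size)
    out = np.empty_like(traj)
    for t, x in enumerate(traj):
        h, C = lstm_cell_step(np.array([x]), h, C, params)
        out[t] = x + (h @ w_out + b_out).item()
    return out
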