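"""Reference LSTM cell, written exactly as the defining equations read.

This is the test oracle for the vectorized network implementation: one
time step, per-gate weight matrices, no batching tricks.  Gate algebra::

    f_t = sigmoid(W_f h_{t-1} + U_f x_t + b_f)      (forget gate)
    i_t = sigmoid(W_i h_{t-1} + U_i x_t + b_i)      (input gate)
    a_t = tanh   (W_a h_{t-1} + U_a x_t + b_a)      (candidate)
    C_t = C_{t-1} * f_t + i_t * a_t                 (memory cell)
    o_t = sigmoid(W_o h_{t-1} + U_o x_t + b_o)      (output gate)
    h_t = o_t * tanh(C_t)                           (hidden state)

with ``*`` the Hadamard (elementwise) product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["LstmCellParams", "lstm_cell_step", "run_reference_chain"]


@dataclass
class LstmCellParams:
    """Per-gate LSTM weights: recurrent ``W_*`` (H, H), input ``U_*``
    (H, D), bias ``b_*`` (H,)."""

    W_f: np.ndarray
    U_f: np.ndarray
    b_f: np.ndarray
    W_i: np.ndarray
    U_i: np.ndarray
    b_i: np.ndarray
    W_a: np.ndarray
    U_a: np.ndarray
    b_a: np.ndarray
    W_o: np.ndarray
    U_o: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, D = self.U_f.shape
        for gate in "fiao":
            W = getattr(self, f"W_{gate}")
            U = getattr(self, f"U_{gate}")
            b = getattr(self, f"b_{gate}")
            if W.shape != (H, H) or U.shape != (H, D) or b.shape != (H,):
                raise ValueError(
                    f"gate {gate}: inconsistent shapes W{W.shape} U{U.shape} b{b.shape}"
                )

    @property
    def hidden_width(self) -> int:
        return self.U_f.shape[0]

    @property
    def input_width(self) -> int:
        return self.U_f.shape[1]


def lstm_cell_step(
    params: LstmCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the cell one time step; returns ``(h_t, C_t)``."""
    p = params
    if x_t.shape != (p.input_width,) or h_prev.shape != (p.hidden_width,):
        raise ValueError("x_t/h_prev shape does not match the parameters")
    f_t = _sigmoid(p.W_f @ h_prev + p.U_f @ x_t + p.b_f)
    i_t = _sigmoid(p.W_i @ h_prev + p.U_i @ x_t + p.b_i)
    a_t = np.tanh(p.W_a @ h_prev + p.U_a @ x_t + p.b_a)
    C_t = C_prev * f_t + i_t * a_t
    o_t = _sigmoid(p.W_o @ h_prev + p.U_o @ x_t + p.b_o)
    h_t = o_t * np.tanh(C_t)
    return h_t, C_t


def run_reference_chain(params: LstmCellParams, xs: np.ndarray) -> np.ndarray:
    """Unroll the cell over a (T, D) input sequence from zero state;
    returns the (T, H) hidden-state trajectory."""
    h = np.zeros(params.hidden_width)
    C = np.zeros(params.hidden_width)
    out = np.empty((len(xs), params.hidden_width))
    for t, x_t in enumerate(xs):
        h, C = lstm_cell_step(params, x_t, h, C)
        out[t] = h
    return out
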