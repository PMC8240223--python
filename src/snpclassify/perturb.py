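"""Targeted input perturbation and projection-matrix recovery.

After the classifier is trained and its weights W* frozen, two further steps
turn the trained network into a better *embedding*:

1. **IFGSM on the embedded training inputs.**  Each embedded training row z_i
   is nudged toward its own true class for M iterations,

       z_i^(m) = z_i^(m-1) - eps * sign( grad_z C_W*(z_i^(m-1), y_c) ),

   which strictly bounds every coordinate's total movement by eps * M.  This
   is the targeted fast gradient sign method run in the loss-*decreasing*
   direction (the target is the correct class, not an adversarial one).

2. **Least-squares recovery of a perturbed projection.**  The perturbed
   embedding X'* is pulled back to a projection matrix by solving
   min_V ||X V - X'*||_F^2 over m x k matrices V.  With m >> n the system is
   underdetermined; the minimum-norm solution U* = X^+ X'* is used, which
   reproduces U^k exactly when X'* is the unperturbed projection and
   interpolates (X U* = X'*) whenever X has full row rank.  Held-out data is
   then embedded with U* instead of U^k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import GenotypeMatrix
from .mlp import MLPModel, evaluate, input_gradient, loss_value

_RANK_RTOL = 1e-12


@dataclass
class PerturbConfig:
    """Step size and iteration budget of the IFGSM update.

    ``epsilon=None`` (default) resolves to a per-column step of
    ``epsilon_rel`` times the column standard deviation of the embedded
    training matrix — embedded features are not standardised, so an absolute
    step would mean very different things for the first and last SVD
    coordinates.  A float ``epsilon`` is used as an absolute step for every
    coordinate.
    """

    epsilon: float | None = None
    epsilon_rel: float = 0.01
    n_iterations: int = 10
    stop_rule: str = "fixed_M"
    plateau_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epsilon is None and self.epsilon_rel <= 0:
            raise ValueError("epsilon_rel must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.stop_rule not in ("fixed_M", "loss_plateau"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass
class PerturbResult:
    """Artifacts of the two perturbation steps."""

    X_prime: np.ndarray
    X_prime_star: np.ndarray
    U_star: np.ndarray
    residual_norm: float
    loss_before: float
    loss_after: float
    epsilon: np.ndarray
    n_iterations: int


def resolve_epsilon(cfg: PerturbConfig, X_prime: np.ndarray) -> np.ndarray:
    """Per-column step sizes implied by the config for this embedded matrix."""
    X_prime = np.asarray(X_prime, dtype=float)
    if cfg.epsilon is not None:
        return np.full(X_prime.shape[1], float(cfg.epsilon))
    sd = X_prime.std(axis=0)
    # degenerate constant columns: fall back to the mean scale so eps > 0
    fallback = sd[sd > 0].mean() if (sd > 0).any() else 1.0
    return cfg.epsilon_rel * np.where(sd > 0, sd, fallback)


def ifgsm_perturb(
    X_prime: np.ndarray,
    Y: np.ndarray,
    model: MLPModel,
    cfg: PerturbConfig,
    loss: str = "mse_softmax",
) -> np.ndarray:
    """Iterated targeted sign-step toward each sample's true class.

    The model is read-only: weights are never touched.  ``sign(0)`` is 0, so
    coordinates with zero gradient stay put.  Every coordinate moves by at
    most ``eps * n_iterations`` in total.
    """
    Z = np.asarray(X_prime, dtype=float).copy()
    Y = np.asarray(Y, dtype=float)
    eps = resolve_epsilon(cfg, Z)
    prev_loss = loss_value(model, Z, Y, loss)
    for _m in range(cfg.n_iterations):
        grad = input_gradient(model, Z, Y, loss)
        if not np.isfinite(grad).all():
            raise FloatingPointError("non-finite input gradient during IFGSM")
        candidate = Z - eps * np.sign(grad)
        if cfg.stop_rule == "loss_plateau":
            # accept the step only if it improves the loss by at least the
            # tolerance, so a plateau leaves the inputs exactly as they were
            cur = loss_value(model, candidate, Y, loss)
            if prev_loss - cur < cfg.plateau_tol:
                break
            prev_loss = cur
        Z = candidate
    return Z


def perturb_projection(
    X_train: GenotypeMatrix | np.ndarray, X_prime_star: np.ndarray
) -> tuple[np.ndarray, float]:
    """Minimum-norm least-squares pullback of a perturbed embedding.

    Solves min_V ||X V - X'*||_F via LAPACK's SVD-based gelsd driver, which
    returns the minimum-norm solution of the (typically underdetermined,
    m >> n) system.  Severe rank deficiency triggers a warning; singular
    values below ``1e-12 * sigma_max`` are truncated by the solver.
    """
    A = X_train.values if isinstance(X_train, GenotypeMatrix) else X_train
    A = np.asarray(A, dtype=float)
    B = np.asarray(X_prime_star, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"row mismatch: X has {A.shape[0]} samples, X'* has {B.shape[0]}"
        )
    U_star, _, rank, s = scipy.linalg.lstsq(
        A, B, cond=_RANK_RTOL, lapack_driver="gelsd"
    )
    if s is not None and s.size and s[-1] < _RANK_RTOL * s[0]:
        warnings.warn(
            f"severely rank-deficient system (sigma_min/sigma_max = "
            f"{s[-1] / s[0]:.2e}); pseudo-inverse truncated at {_RANK_RTOL:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    residual = float(np.linalg.norm(A @ U_star - B, ord="fro"))
    return U_star, residual


def perturb(
    X_train: GenotypeMatrix | np.ndarray,
    X_prime: np.ndarray,
    Y: np.ndarray,
    model: MLPModel,
    cfg: PerturbConfig | None = None,
    loss: str = "mse_softmax",
) -> PerturbResult:
    """Run both steps (IFGSM + projection recovery) and collect artifacts."""
    cfg = cfg or PerturbConfig()
    X_star = ifgsm_perturb(X_prime, Y, model, cfg, loss=loss)
    U_star, residual = perturb_projection(X_train, X_star)
    return PerturbResult(
        X_prime=np.asarray(X_prime, dtype=float),
        X_prime_star=X_star,
        U_star=U_star,
        residual_norm=residual,
        loss_before=loss_value(model, X_prime, Y, loss),
        loss_after=loss_value(model, X_star, Y, loss),
        epsilon=resolve_epsilon(cfg, np.asarray(X_prime, dtype=float)),
        n_iterations=cfg.n_iterations,
    )


def perturbation_report(
    result: PerturbResult,
    model: MLPModel,
    Y: np.ndarray,
    X_train: GenotypeMatrix | np.ndarray,
    loss: str = "mse_softmax",
) -> dict:
    """Training-side loss and accuracy at the three stages of the method.

    Reports the frozen model's loss/accuracy on the original embedding X',
    on the perturbed embedding X'*, and on X . U* (the embedding actually
    used at test time).
    """
    A = X_train.values if isinstance(X_train, GenotypeMatrix) else X_train
    A = np.asarray(A, dtype=float)
    y_idx = np.argmax(Y, axis=1)
    stages = {
        "original": result.X_prime,
        "perturbed": result.X_prime_star,
        "projected": A @ result.U_star,
    }
    report: dict = {
        "epsilon_max": float(np.max(result.epsilon)),
        "epsilon_min": float(np.min(result.epsilon)),
        "n_iterations": result.n_iterations,
        "residual_norm": result.residual_norm,
    }
    for name, Z in stages.items():
        report[f"loss_{name}"] = loss_value(model, Z, Y, loss)
        report[f"accuracy_{name}"] = evaluate(model, Z, y_idx)["accuracy"]
    return report
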