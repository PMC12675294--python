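"""Joint optimization of the velocity field and the latent shape codes.

One trainable latent code per cohort shape conditions a shared velocity
network (an auto-decoder: there is no encoder, the codes are parameters).
Each step samples a batch of shapes, subsamples M points per cloud with
adaptive retention of the worst-fitting points, integrates the flow
forward (sources) and backward (template), and minimizes

    mean_i E(S_i, T; phi_i) + w_z ||Z||^2 + w_Theta ||Theta||^2 + w_v L_reg

with E the bidirectional mapping error under the configured attachment
measure and L_reg the kinetic energy summed over all logged velocities.
At test time only the code of the unseen shape is optimized (Adam at a
50x learning rate, then L-BFGS), with the network frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._tape import Var, as_var, concat
from .attachment import SinkhornConfig, evaluate_measure, measure_loss
from .cloud import WeightedPointCloud
from .integrator import forward_map, inverse_map_explicit
from .network import NetConfig, VelocityFieldModel, lerp_code

__all__ = [
    "TrainConfig",
    "CodeBank",
    "TrainingDiverged",
    "Adam",
    "init_model_and_codes",
    "point_sample",
    "make_batches",
    "regularizer_value",
    "total_loss_value",
    "train",
    "infer_latent",
    "InferenceResult",
    "kfold_splits",
]


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 8
    sample_points: int = 2000
    adaptive_fraction: float = 0.15
    lr: float = 1e-3
    w_z: float = 1e-3
    w_v: float = 1e-4
    w_theta: float = 0.0  # Theta penalty exists in the loss; weight exposed
    w_n: float = 1e-2
    measure: str = "cd"
    test_measure: str | None = None  # e.g. fall back to "cd" when training "ncd"
    K: int = 10
    seed: int = 0
    infer_adam_epochs: int = 100
    infer_lbfgs_epochs: int = 10
    infer_lr_factor: float = 50.0
    sinkhorn: SinkhornConfig = field(default_factory=SinkhornConfig)

    def __post_init__(self):
        if not 0 <= self.adaptive_fraction < 1:
            raise ValueError("adaptive_fraction must lie in [0, 1)")
        if self.batch_size < 1 or self.sample_points < 1:
            raise ValueError("batch_size and sample_points must be >= 1")


@dataclass
class CodeBank:
    """One trainable latent code per training shape."""

    codes: list[Var]
    labels: list[str]
    init_std: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        """Codes as columns: N_z x N_s."""
        return np.stack([c.data for c in self.codes], axis=1)

    def sqnorm_value(self) -> float:
        return float(sum((c.data**2).sum() for c in self.codes))

    def __len__(self) -> int:
        return len(self.codes)


class TrainingDiverged(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """First-order adaptive-moment optimizer over named tape variables."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}

    def step(self, named: dict[str, Var]) -> None:
        for name, p in named.items():
            if p.grad is None:
                continue
            m, v, t = self.state.get(name, (np.zeros_like(p.data), np.zeros_like(p.data), 0))
            t += 1
            m = self.beta1 * m + (1 - self.beta1) * p.grad
            v = self.beta2 * v + (1 - self.beta2) * p.grad**2
            mh = m / (1 - self.beta1**t)
            vh = v / (1 - self.beta2**t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
            self.state[name] = (m, v, t)


# ---------------------------------------------------------------------------
# initialization, sampling, batching


def init_model_and_codes(
    net_config: NetConfig, shapes: list[WeightedPointCloud], seed: int = 0
) -> tuple[VelocityFieldModel, CodeBank]:
    """Kaiming-normal network (zeroed flow head) and Gaussian codes with
    per-entry variance 2/N_z, all reproducible from the seed."""
    if len(shapes) < 1:
        raise ValueError("need at least one training shape")
    rng = np.random.default_rng(seed)
    model = VelocityFieldModel.initialize(net_config, rng)
    std = np.sqrt(2.0 / net_config.n_z)
    codes = [
        Var(rng.normal(0.0, std, size=net_config.n_z), requires_grad=True) for _ in shapes
    ]
    labels = [s.label or f"shape_{i}" for i, s in enumerate(shapes)]
    return model, CodeBank(codes=codes, labels=labels, init_std=std)


def point_sample(
    n_points: int,
    pointwise_loss: np.ndarray | None,
    M: int,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-stage sample: floor(a*M) current top-loss points are retained,
    the remaining ceil((1-a)*M) are drawn uniformly without replacement.

    With no pointwise information (epoch 0, or measures without a pointwise
    decomposition) the sample is fully uniform.
    """
    if M > n_points:
        warnings.warn("requested more points than the cloud holds; using all")
        return np.arange(n_points)
    if pointwise_loss is None or a == 0 or not np.any(pointwise_loss):
        return rng.choice(n_points, size=M, replace=False)
    n_keep = int(np.floor(a * M))
    order = np.argsort(-pointwise_loss, kind="stable")
    keep = order[:n_keep]
    rest = np.setdiff1d(np.arange(n_points), keep, assume_unique=False)
    uniform = rng.choice(rest, size=M - n_keep, replace=False)
    return np.concatenate([keep, uniform])


def make_batches(n_shapes: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seed-shuffled partition of the cohort: floor(N_s/B) batches (at least
    one) with sizes as even as possible, summing exactly to N_s; every shape
    appears exactly once per epoch."""
    if n_shapes < 1:
        raise ValueError("n_shapes must be >= 1")
    perm = rng.permutation(n_shapes)
    n_batches = max(1, n_shapes // batch_size)
    base, extra = divmod(n_shapes, n_batches)
    sizes = [base + 1] * extra + [base] * (n_batches - extra)
    out, off = [], 0
    for s in sizes:
        out.append(perm[off : off + s])
        off += s
    return out


# ---------------------------------------------------------------------------
# loss bookkeeping (numpy-side, for logging and tests)


def regularizer_value(trajectories) -> float:
    """L_reg: summed squared velocities over all logged trajectory steps."""
    total = 0.0
    for traj in trajectories:
        if traj.velocities is None:
            raise ValueError("trajectory carries no velocity log")
        total += float((traj.velocities**2).sum())
    return total


def total_loss_value(
    batch_errors: np.ndarray, code_sqnorm: float, theta_sqnorm: float, l_reg: float,
    config: TrainConfig,
) -> float:
    """Scalar loss: mean bidirectional error + weighted penalties."""
    return (
        float(np.mean(batch_errors))
        + config.w_z * code_sqnorm
        + config.w_theta * theta_sqnorm
        + config.w_v * l_reg
    )


# ---------------------------------------------------------------------------
# batched differentiable integration (shapes stacked along the point axis)


def _batched_field(model, codes: list[Var], x: Var, offsets: list[int]) -> Var:
    parts = []
    for i, code in enumerate(codes):
        xs = x[offsets[i] : offsets[i + 1]]
        parts.append(lerp_code(xs, code, model.config.g_z))
    zbar = parts[0] if len(parts) == 1 else concat(parts, axis=0)
    return model.velocity(x, zbar)


def _batched_forward(model, codes, x0: Var, offsets, K):
    states, vels = [x0], []
    for _ in range(K):
        v = _batched_field(model, codes, states[-1], offsets)
        vels.append(v)
        states.append(states[-1] + v * (1.0 / K))
    return states, vels


def _batched_backward(model, codes, xK: Var, offsets, K):
    states, vels = [xK], []
    for _ in range(K):
        x = states[-1]
        inner = x - _batched_field(model, codes, x, offsets) * (1.0 / K)
        v = _batched_field(model, codes, inner, offsets)
        vels.append(v)
        states.append(x - v * (1.0 / K))
    return states, vels


# ---------------------------------------------------------------------------
# training


def train(
    shapes: list[WeightedPointCloud],
    template: WeightedPointCloud,
    net_config: NetConfig | None = None,
    config: TrainConfig | None = None,
    model: VelocityFieldModel | None = None,
    codebank: CodeBank | None = None,
    callback=None,
) -> tuple[VelocityFieldModel, CodeBank, dict]:
    """Cohort registration training loop.

    Per epoch and batch: resample a template sub-cloud (shared across the
    batch), adaptively resample each source, integrate sources forward and
    the template backward under each shape's code, assemble the loss and
    take Adam steps on Theta and on the batch's codes only.
    """
    net_config = net_config or NetConfig()
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    if model is None or codebank is None:
        model, codebank = init_model_and_codes(net_config, shapes, seed=config.seed)
    n_s = len(shapes)
    M = config.sample_points
    K = config.K
    a = config.adaptive_fraction
    measure = config.measure.lower()
    pointwise_ok = measure not in ("sd", "sdw")

    opt_theta = Adam(config.lr)
    opt_codes = Adam(config.lr)

    src_pw = [np.zeros(len(s)) for s in shapes]
    tmpl_pw_per_shape = [np.zeros(len(template)) for _ in shapes]
    tmpl_pw = np.zeros(len(template))

    history: dict[str, list] = {
        "total": [], "data": [], "code_term": [], "theta_term": [], "reg_term": [],
        "epoch_total": [],
    }

    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in make_batches(n_s, config.batch_size, rng):
            t_idx = point_sample(len(template), tmpl_pw if pointwise_ok else None, M, a, rng)
            t_sub = template.subsample(t_idx)
            codes = [codebank.codes[i] for i in batch]

            # stack the batch's sampled source points
            s_idx_list, x0_list = [], []
            for i in batch:
                s_idx = point_sample(len(shapes[i]), src_pw[i] if pointwise_ok else None, M, a, rng)
                s_idx_list.append(s_idx)
                x0_list.append(shapes[i].points[s_idx])
            sizes = [len(x) for x in x0_list]
            offsets = list(np.concatenate([[0], np.cumsum(sizes)]))
            x0 = as_var(np.concatenate(x0_list, axis=0))

            f_states, f_vels = _batched_forward(model, codes, x0, offsets, K)
            # template points replicated once per shape in the batch
            tn = len(t_idx)
            t_off = [tn * i for i in range(len(batch) + 1)]
            tK = as_var(np.tile(t_sub.points, (len(batch), 1)))
            b_states, b_vels = _batched_backward(model, codes, tK, t_off, K)

            # per-shape bidirectional errors: mapped sub-clouds are compared
            # against the FULL opposite cloud (the sub-sampling caps the
            # mapping cost; the attachment stays exact on the target side)
            errors = []
            for bi, i in enumerate(batch):
                Xf = f_states[-1][offsets[bi] : offsets[bi + 1]]
                src_sub = shapes[i].subsample(s_idx_list[bi])
                # optimal transport scales quadratically: keep both sides sampled
                d_target = t_sub if not pointwise_ok else template
                i_target = src_sub if not pointwise_ok else shapes[i]
                d_loss, d_pw = measure_loss(
                    measure, Xf, d_target,
                    source_normals=src_sub.normals, source_weights=src_sub.weights,
                    w_n=config.w_n, sinkhorn=config.sinkhorn,
                )
                Xb = b_states[-1][t_off[bi] : t_off[bi + 1]]
                i_loss, i_pw = measure_loss(
                    measure, Xb, i_target,
                    source_normals=t_sub.normals, source_weights=t_sub.weights,
                    w_n=config.w_n, sinkhorn=config.sinkhorn,
                )
                errors.append(d_loss + i_loss)
                if pointwise_ok:
                    src_pw[i][s_idx_list[bi]] = d_pw
                    tmpl_pw_per_shape[i][t_idx] = i_pw

            acc = errors[0]
            for e in errors[1:]:
                acc = acc + e
            data_term = acc * (1.0 / len(errors))

            # kinetic-energy regularizer over all logged velocities
            reg = None
            for v in f_vels + b_vels:
                s = (v * v).sum()
                reg = s if reg is None else reg + s

            # code penalty: batch codes on the tape, rest as a constant
            batch_code_sq = None
            for c in codes:
                s = (c * c).sum()
                batch_code_sq = s if batch_code_sq is None else batch_code_sq + s
            other_sq = codebank.sqnorm_value() - batch_code_sq.item()

            loss = data_term + config.w_v * reg + config.w_z * (batch_code_sq + other_sq)
            theta_sq_val = float(sum((p.data**2).sum() for p in model.params.values()))
            if config.w_theta > 0:
                loss = loss + config.w_theta * model.param_sqnorm()

            total_val = loss.item()
            if not np.isfinite(total_val):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; last data term "
                    f"{data_term.item():.3e}"
                )

            model.zero_grad()
            for c in codes:
                c.grad = None
            loss.backward()
            opt_theta.step(model.params)
            opt_codes.step({f"code_{i}": codebank.codes[i] for i in batch})

            history["total"].append(total_val)
            history["data"].append(data_term.item())
            history["code_term"].append(config.w_z * (batch_code_sq.item() + other_sq))
            history["theta_term"].append(config.w_theta * theta_sq_val)
            history["reg_term"].append(config.w_v * reg.item())
            epoch_losses.append(total_val)

        if pointwise_ok:
            tmpl_pw = np.mean(tmpl_pw_per_shape, axis=0)
        history["epoch_total"].append(float(np.mean(epoch_losses)))
        if callback is not None:
            callback(epoch, history)

    return model, codebank, history


# ---------------------------------------------------------------------------
# test-time latent inference


@dataclass
class InferenceResult:
    code: np.ndarray
    forward_mapped: WeightedPointCloud
    inverse_mapped: WeightedPointCloud
    error: float
    lbfgs_converged: bool
    history: list


def _inference_objective(
    model, code: Var, src_sub, tmpl_sub, src_full, tmpl_full, config, measure
):
    """Bidirectional loss + code/kinetic penalties for one shape (tape).

    Sub-clouds are integrated; decomposable measures compare them against
    the full opposite cloud (as in training)."""
    K = config.K
    f_states, f_vels = _batched_forward(
        model, [code], as_var(src_sub.points), [0, len(src_sub)], K
    )
    b_states, b_vels = _batched_backward(
        model, [code], as_var(tmpl_sub.points), [0, len(tmpl_sub)], K
    )
    pointwise_ok = measure not in ("sd", "sdw")
    d_loss, d_pw = measure_loss(
        measure, f_states[-1], tmpl_full if pointwise_ok else tmpl_sub,
        source_normals=src_sub.normals, source_weights=src_sub.weights,
        w_n=config.w_n, sinkhorn=config.sinkhorn,
    )
    i_loss, i_pw = measure_loss(
        measure, b_states[-1], src_full if pointwise_ok else src_sub,
        source_normals=tmpl_sub.normals, source_weights=tmpl_sub.weights,
        w_n=config.w_n, sinkhorn=config.sinkhorn,
    )
    reg = None
    for v in f_vels + b_vels:
        s = (v * v).sum()
        reg = s if reg is None else reg + s
    loss = d_loss + i_loss + config.w_z * (code * code).sum() + config.w_v * reg
    return loss, d_pw, i_pw


def infer_latent(
    test_cloud: WeightedPointCloud,
    template: WeightedPointCloud,
    model: VelocityFieldModel,
    config: TrainConfig | None = None,
) -> InferenceResult:
    """Optimize only the latent code of an unseen shape (Theta frozen).

    Adaptive-moment phase at a learning rate ``infer_lr_factor`` times the
    training one, then a quasi-Newton (L-BFGS) polish on a fixed subsample;
    on line-search failure the best first-order iterate is returned.
    """
    config = config or TrainConfig()
    measure = (config.test_measure or config.measure).lower()
    pointwise_ok = measure not in ("sd", "sdw")
    rng = np.random.default_rng(config.seed)
    n_z = model.config.n_z
    code = Var(np.zeros(n_z), requires_grad=True)

    # freeze Theta: drop it from the tape entirely
    frozen = {k: p.requires_grad for k, p in model.params.items()}
    for p in model.params.values():
        p.requires_grad = False
    M = min(config.sample_points, len(test_cloud), len(template))
    src_pw = np.zeros(len(test_cloud))
    tmpl_pw = np.zeros(len(template))
    opt = Adam(config.lr * config.infer_lr_factor)
    hist = []
    try:
        for _ in range(config.infer_adam_epochs):
            s_idx = point_sample(len(test_cloud), src_pw if pointwise_ok else None,
                                 M, config.adaptive_fraction, rng)
            t_idx = point_sample(len(template), tmpl_pw if pointwise_ok else None,
                                 M, config.adaptive_fraction, rng)
            src_sub = test_cloud.subsample(s_idx)
            t_sub = template.subsample(t_idx)
            loss, d_pw, i_pw = _inference_objective(
                model, code, src_sub, t_sub, test_cloud, template, config, measure
            )
            code.grad = None
            loss.backward()
            opt.step({"code": code})
            if pointwise_ok and d_pw is not None:
                src_pw[s_idx] = d_pw
                tmpl_pw[t_idx] = i_pw
            hist.append(loss.item())

        # quasi-Newton polish on a fixed subsample (deterministic objective)
        s_idx = point_sample(len(test_cloud), src_pw if pointwise_ok else None,
                             M, config.adaptive_fraction, rng)
        t_idx = point_sample(len(template), tmpl_pw if pointwise_ok else None,
                             M, config.adaptive_fraction, rng)
        src_sub = test_cloud.subsample(s_idx)
        t_sub = template.subsample(t_idx)
        adam_code = code.data.copy()

        def fun(zvec):
            cv = Var(zvec, requires_grad=True)
            loss, _, _ = _inference_objective(
                model, cv, src_sub, t_sub, test_cloud, template, config, measure
            )
            loss.backward()
            return loss.item(), cv.grad.copy()

        lbfgs_ok = True
        if config.infer_lbfgs_epochs > 0:
            res = minimize(
                fun, code.data, jac=True, method="L-BFGS-B",
                options={"maxiter": config.infer_lbfgs_epochs, "maxcor": 10},
            )
            lbfgs_ok = bool(res.success) or res.status == 1  # status 1: maxiter reached
            f_adam, _ = fun(adam_code)
            if lbfgs_ok and res.fun <= f_adam:
                code.data = res.x
            else:
                lbfgs_ok = False
                code.data = adam_code
            hist.append(float(min(res.fun, f_adam)))
    finally:
        for k, p in model.params.items():
            p.requires_grad = frozen[k]

    fwd = forward_map(test_cloud.points, model, code.data, config.K)
    inv = inverse_map_explicit(template.points, model, code.data, config.K)
    fwd_cloud = test_cloud.with_points(fwd.endpoint)
    inv_cloud = template.with_points(inv.endpoint)
    err = (
        evaluate_measure("cd", fwd_cloud, template).total
        + evaluate_measure("cd", inv_cloud, test_cloud).total
    )
    return InferenceResult(
        code=code.data.copy(),
        forward_mapped=fwd_cloud,
        inverse_mapped=inv_cloud,
        error=err,
        lbfgs_converged=lbfgs_ok,
        history=hist,
    )


# ---------------------------------------------------------------------------
# cohort splitting helper


def kfold_splits(n_shapes: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train, test) index splits; orchestration at scale is out of scope."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_shapes)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train_idx = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train_idx, test))
    return out
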