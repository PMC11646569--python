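"""Teacher-student knowledge-distillation CNN for binding prediction.

The teacher is a three-block CNN (64/128/256 filters, 3x3 kernels,
stride (2,2), LeakyReLU alpha=0.2, 2x2 max-pool with stride 1) over the
pad_rows x 4 x 1 dihedral-angle input, ending in a hidden dense layer and
a single sigmoid unit.  The student mirrors the topology with 16/32/64
filters.  Distillation trains the student against a convex combination of
the hard binary cross-entropy to ground-truth labels and the
KL divergence between temperature-softened teacher and student output
distributions (Hinton-style, soft term scaled by T^2).

The public surface follows the Model/Results idiom: build a
:class:`BindingDistillationModel` from a feature tensor and labels, call
``fit()`` and work with the returned :class:`BindingDistillationResults`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .featurize import PairedInput, stack_inputs

__all__ = [
    "TeacherConfig",
    "StudentConfig",
    "DistillConfig",
    "DistillerState",
    "BindingDistillationModel",
    "BindingDistillationResults",
    "build_teacher",
    "build_student",
    "bce",
    "distillation_loss",
    "total_student_loss",
    "train",
    "predict",
]

EPS = 1e-7  # probability clip before any log


@dataclass(frozen=True)
class TeacherConfig:
    conv_filters: tuple[int, int, int] = (64, 128, 256)
    kernel: tuple[int, int] = (3, 3)
    conv_stride: tuple[int, int] = (2, 2)
    leaky_slope: float = 0.2
    pool: tuple[int, int] = (2, 2)
    pool_stride: tuple[int, int] = (1, 1)
    dense_hidden: int = 32

    def __post_init__(self):
        if any(f <= 0 for f in self.conv_filters):
            raise ValueError("filter counts must be positive")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must lie in (0, 1)")


@dataclass(frozen=True)
class StudentConfig(TeacherConfig):
    conv_filters: tuple[int, int, int] = (16, 32, 64)


@dataclass(frozen=True)
class DistillConfig:
    alpha: float = 0.5       # weight of the hard (BCE) loss
    temperature: float = 2.0
    learning_rate: float = 1e-3
    epochs: int = 20         # per phase (teacher, then student)
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _build_cnn(config: TeacherConfig, input_shape: tuple[int, int, int],
               rng: np.random.Generator) -> nn.Sequential:
    h, w, c = input_shape
    kh, kw = config.kernel
    if h < kh or w < 1:
        raise ValueError("input too small for architecture")
    layers: list[nn.Layer] = []
    c_in = c
    for filters in config.conv_filters:
        layers += [
            nn.Conv2D(c_in, filters, kernel=config.kernel, stride=config.conv_stride,
                      rng=rng, leaky_slope=config.leaky_slope),
            nn.LeakyReLU(config.leaky_slope),
            nn.MaxPool2D(pool=config.pool, stride=config.pool_stride),
        ]
        c_in = filters
    layers.append(nn.Flatten())
    flat = nn.Sequential(layers).forward(
        np.zeros((1, h, w, c), dtype=nn.DTYPE), train=False
    ).shape[1]
    layers += [
        nn.Dense(flat, config.dense_hidden, rng=rng),
        nn.LeakyReLU(config.leaky_slope),
        nn.Dense(config.dense_hidden, 1, rng=rng),
    ]
    # Final layer emits the logit; sigmoid applied by the model wrapper so
    # loss gradients are computed at the logit for numerical stability.
    return nn.Sequential(layers)


def build_teacher(config: TeacherConfig = TeacherConfig(),
                  input_shape: tuple[int, int, int] = (17, 4, 1),
                  rng: np.random.Generator | int | None = None) -> nn.Sequential:
    """Parameterised teacher network (logit output)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _build_cnn(config, input_shape, rng)


def build_student(config: StudentConfig = StudentConfig(),
                  input_shape: tuple[int, int, int] = (17, 4, 1),
                  rng: np.random.Generator | int | None = None) -> nn.Sequential:
    """Parameterised student network (same topology, fewer filters)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _build_cnn(config, input_shape, rng)


# ----------------------------------------------------------------------
# Losses


def _clip(p):
    return np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)


def _soften(p, temperature: float):
    """Temperature-soften a Bernoulli probability via its logit."""
    logit = np.log(p) - np.log1p(-p)
    return 1.0 / (1.0 + np.exp(-logit / temperature))


def bce(y, p) -> float:
    """Mean binary cross-entropy, probabilities clipped at 1e-7."""
    y = np.asarray(y, dtype=float)
    p = _clip(p)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


def distillation_loss(teacher_prob, student_prob, temperature: float = 2.0) -> float:
    """KL divergence between temperature-softened Bernoulli outputs.

    With p~, q~ the softened teacher/student probabilities, returns the
    mean of p~ ln(p~/q~) + (1-p~) ln((1-p~)/(1-q~)); at T=1 this is the
    plain Bernoulli KL. Zero iff the probabilities agree (within the clip
    tolerance), strictly positive otherwise.
    """
    p = _soften(_clip(teacher_prob), temperature)
    q = _soften(_clip(student_prob), temperature)
    kl = p * (np.log(p) - np.log(q)) + (1 - p) * (np.log1p(-p) - np.log1p(-q))
    return float(np.mean(kl))


def total_student_loss(y, student_prob, teacher_prob, config: DistillConfig) -> float:
    """alpha * BCE(y, student) + (1-alpha) * T^2 * KL(teacher~ || student~)."""
    a, t = config.alpha, config.temperature
    return a * bce(y, student_prob) + (1 - a) * t * t * distillation_loss(
        teacher_prob, student_prob, t
    )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ----------------------------------------------------------------------
# State / Results / Model


@dataclass
class DistillerState:
    """Trained parameters plus everything needed to reuse them safely."""

    teacher_weights: list[np.ndarray]
    student_weights: list[np.ndarray]
    teacher_config: TeacherConfig
    student_config: StudentConfig
    distill_config: DistillConfig
    input_shape: tuple[int, int, int]
    normalized: bool
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"teacher_{i}": w for i, w in enumerate(self.teacher_weights)}
        arrays |= {f"student_{i}": w for i, w in enumerate(self.student_weights)}
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "teacher_config": asdict(self.teacher_config),
            "student_config": asdict(self.student_config),
            "distill_config": asdict(self.distill_config),
            "input_shape": list(self.input_shape),
            "normalized": self.normalized,
            "history": self.history,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "DistillerState":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        npz = np.load(directory / "weights.npz")
        def _tuples(d):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        n_t = sum(1 for k in npz.files if k.startswith("teacher_"))
        n_s = sum(1 for k in npz.files if k.startswith("student_"))
        return cls(
            teacher_weights=[npz[f"teacher_{i}"] for i in range(n_t)],
            student_weights=[npz[f"student_{i}"] for i in range(n_s)],
            teacher_config=TeacherConfig(**_tuples(meta["teacher_config"])),
            student_config=StudentConfig(**_tuples(meta["student_config"])),
            distill_config=DistillConfig(**meta["distill_config"]),
            input_shape=tuple(meta["input_shape"]),
            normalized=bool(meta["normalized"]),
            history=meta["history"],
        )

    def networks(self) -> tuple[nn.Sequential, nn.Sequential]:
        teacher = build_teacher(self.teacher_config, self.input_shape, rng=0)
        student = build_student(self.student_config, self.input_shape, rng=0)
        teacher.set_weights(self.teacher_weights)
        student.set_weights(self.student_weights)
        return teacher, student


def _as_tensor(inputs) -> np.ndarray:
    if isinstance(inputs, np.ndarray):
        x = inputs
        if x.ndim == 3:
            x = x[..., None]
        return x.astype(nn.DTYPE)
    if len(inputs) and isinstance(inputs[0], PairedInput):
        return stack_inputs(list(inputs))
    return np.asarray(inputs, dtype=nn.DTYPE)


class BindingDistillationModel:
    """Knowledge-distillation binding classifier, Model/Results style.

    Parameters
    ----------
    inputs : array (n, pad_rows, 4[, 1]) or list of PairedInput
        Dihedral feature matrices.
    labels : array of {0, 1}
        Binding labels, one per input.
    """

    def __init__(self, inputs, labels,
                 teacher_config: TeacherConfig = TeacherConfig(),
                 student_config: StudentConfig = StudentConfig(),
                 distill_config: DistillConfig = DistillConfig(),
                 normalized: bool = True):
        self.x = _as_tensor(inputs)
        self.y = np.asarray(labels, dtype=float).reshape(-1, 1)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("inputs and labels length mismatch")
        self.teacher_config = teacher_config
        self.student_config = student_config
        self.distill_config = distill_config
        self.normalized = normalized

    @classmethod
    def from_records(cls, records, paired_inputs, **kwargs) -> "BindingDistillationModel":
        """Build from PairRecords plus their featurized PairedInputs."""
        labels = [r.label for r in records]
        normalized = bool(paired_inputs and paired_inputs[0].normalized)
        return cls(paired_inputs, labels, normalized=normalized, **kwargs)

    # -- training -------------------------------------------------------

    def _epoch_batches(self, rng, n):
        order = rng.permutation(n)
        bs = self.distill_config.batch_size
        for start in range(0, n, bs):
            yield order[start : start + bs]

    def fit(self, verbose: bool = False) -> "BindingDistillationResults":
        """Two-phase training: teacher on hard labels, then distillation.

        Phase 1 fits the teacher with BCE/Adam. Phase 2 freezes the
        teacher and fits the student against
        ``alpha * BCE + (1-alpha) * T^2 * KL`` with the same optimiser.
        """
        labels = np.unique(self.y)
        if labels.size < 2:
            raise ValueError("degenerate training set: a single class present")
        cfg = self.distill_config
        rng = np.random.default_rng(cfg.seed)
        input_shape = self.x.shape[1:]
        teacher = build_teacher(self.teacher_config, input_shape, rng=rng)
        student = build_student(self.student_config, input_shape, rng=rng)
        n = self.x.shape[0]
        history: dict[str, list[float]] = {
            "teacher_loss": [], "student_loss": [], "student_bce": [],
            "distill_loss": [], "binary_accuracy": [],
        }

        opt_t = nn.Adam(teacher, lr=cfg.learning_rate)
        for epoch in range(cfg.epochs):
            losses = []
            for idx in self._epoch_batches(rng, n):
                xb, yb = self.x[idx], self.y[idx]
                p = _sigmoid(teacher.forward(xb))
                losses.append(bce(yb, p) * len(idx))
                teacher.backward((p - yb).astype(nn.DTYPE) / len(idx))
                opt_t.step()
            history["teacher_loss"].append(float(np.sum(losses) / n))
            if verbose:
                print(f"teacher epoch {epoch}: loss={history['teacher_loss'][-1]:.4f}")

        a, t = cfg.alpha, cfg.temperature
        opt_s = nn.Adam(student, lr=cfg.learning_rate)
        for epoch in range(cfg.epochs):
            tot, hard, soft, correct = [], [], [], 0
            for idx in self._epoch_batches(rng, n):
                xb, yb = self.x[idx], self.y[idx]
                p_t = _sigmoid(teacher.forward(xb, train=False))
                z_s = student.forward(xb)
                p_s = _sigmoid(z_s)
                hard_l = bce(yb, p_s)
                soft_l = distillation_loss(p_t, p_s, t)
                tot.append((a * hard_l + (1 - a) * t * t * soft_l) * len(idx))
                hard.append(hard_l * len(idx))
                soft.append(soft_l * len(idx))
                correct += int(np.sum((p_s >= 0.5) == (yb >= 0.5)))
                p_soft_t = _soften(_clip(p_t), t)
                q_soft_s = _soften(_clip(p_s), t)
                grad = a * (p_s - yb) + (1 - a) * t * (q_soft_s - p_soft_t)
                student.backward(grad.astype(nn.DTYPE) / len(idx))
                opt_s.step()
            history["student_loss"].append(float(np.sum(tot) / n))
            history["student_bce"].append(float(np.sum(hard) / n))
            history["distill_loss"].append(float(np.sum(soft) / n))
            history["binary_accuracy"].append(correct / n)
            if verbose:
                print(
                    f"student epoch {epoch}: loss={history['student_loss'][-1]:.4f} "
                    f"acc={history['binary_accuracy'][-1]:.3f}"
                )

        state = DistillerState(
            teacher_weights=teacher.get_weights(),
            student_weights=student.get_weights(),
            teacher_config=self.teacher_config,
            student_config=self.student_config,
            distill_config=cfg,
            input_shape=tuple(input_shape),
            normalized=self.normalized,
            history=history,
        )
        return BindingDistillationResults(self, state)


class BindingDistillationResults:
    """Fitted distillation model: trained parameters, history, prediction."""

    def __init__(self, model: BindingDistillationModel | None, state: DistillerState):
        self.model = model
        self.state = state
        self._teacher, self._student = state.networks()

    @classmethod
    def from_checkpoint(cls, directory) -> "BindingDistillationResults":
        return cls(None, DistillerState.load(directory))

    @property
    def history(self) -> dict[str, list[float]]:
        return self.state.history

    def predict(self, inputs, use: str = "student", batch_size: int = 512) -> np.ndarray:
        """Binding probabilities in (0,1), order-preserving."""
        if use not in ("teacher", "student"):
            raise ValueError("use must be 'teacher' or 'student'")
        x = _as_tensor(inputs)
        if x.shape[0] == 0:
            return np.empty(0)
        if tuple(x.shape[1:]) != tuple(self.state.input_shape):
            raise ValueError(
                f"input shape mismatch: got {tuple(x.shape[1:])}, "
                f"trained on {tuple(self.state.input_shape)}"
            )
        net = self._teacher if use == "teacher" else self._student
        out = [
            _sigmoid(net.forward(x[s : s + batch_size], train=False))
            for s in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out).ravel()

    def n_params(self, use: str = "student") -> int:
        net = self._teacher if use == "teacher" else self._student
        return net.n_params()

    def save(self, directory) -> None:
        self.state.save(directory)

    def summary(self) -> str:
        """Plain-text fit summary in the Results-object tradition."""
        h = self.state.history
        cfg = self.state.distill_config
        lines = [
            "Knowledge-Distillation Binding Model Results",
            "=" * 46,
            f"Input shape:            {tuple(self.state.input_shape)}",
            f"Teacher parameters:     {self._teacher.n_params():,}",
            f"Student parameters:     {self._student.n_params():,}",
            f"alpha (hard weight):    {cfg.alpha}",
            f"temperature:            {cfg.temperature}",
            f"epochs per phase:       {cfg.epochs}",
            f"seed:                   {cfg.seed}",
        ]
        if h.get("teacher_loss"):
            lines.append(f"final teacher BCE:      {h['teacher_loss'][-1]:.4f}")
        if h.get("student_loss"):
            lines += [
                f"final student loss:     {h['student_loss'][-1]:.4f}",
                f"final student BCE:      {h['student_bce'][-1]:.4f}",
                f"final distill KL:       {h['distill_loss'][-1]:.4f}",
                f"final train accuracy:   {h['binary_accuracy'][-1]:.4f}",
            ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# Functional wrappers


def train(paired_inputs, labels, config: DistillConfig = DistillConfig(),
          **model_kwargs) -> DistillerState:
    """Fit the teacher/student pair and return the trained state."""
    model = BindingDistillationModel(paired_inputs, labels,
                                     distill_config=config, **model_kwargs)
    return model.fit().state


def predict(state: DistillerState, inputs, use: str = "student") -> np.ndarray:
    """Score inputs with a trained state (probabilities in (0,1))."""
    return BindingDistillationResults(None, state).predict(inputs, use=use)
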