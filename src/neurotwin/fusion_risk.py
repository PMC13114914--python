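"""Fog-layer packet gate and cloud-side EEG-MRI feature fusion.

Packet gate
-----------
EEG feature packets arriving from the edge carry a UTC timestamp, device
and session identifiers, the feature vector (including the FHI), and an
HMAC-SHA256 signature over the payload computed with a pre-shared key.
``validate_packet`` checks, in order: known device -> signature -> age
(packets older than 3 s are discarded as stale/replays).  Accepted
packets are scored by a two-class softmax risk model, R = softmax(Wx+b)
restricted to the high-risk component; packets with R > 0.75 (strict)
are forwarded as high priority.

Fusion
------
Each Functional Health Vector pairs with the most recent structural
embedding S (the 64-dim pooled patch-transformer representation of the
latest MRI scan) whose timestamp does not exceed the FHV's.  The pair is
concatenated (S then FHV, 66 values) and passed through a shallow MLP —
66 -> 128 ReLU -> 64 ReLU -> 64 linear — producing the fused state
vector Z(t); a single logistic head on Z(t) yields the composite risk
score in (0, 1).
"""

from __future__ import annotations

import hashlib
import hmac
import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from . import nn

__all__ = [
    "FeaturePacket", "ValidationResult", "validate_packet", "sign_packet",
    "RiskModel", "RiskScore", "risk_score",
    "FusionMLP", "FusedState", "fuse", "CompositeRiskHead", "composite_risk",
    "train_composite_risk", "align",
    "FORWARD_THRESHOLD", "MAX_PACKET_DELAY_S",
]

#: packets older than this are rejected as stale or replayed
MAX_PACKET_DELAY_S = 3.0

#: strict forwarding threshold on the high-risk softmax component
FORWARD_THRESHOLD = 0.75


# --------------------------------------------------------------- packets --
@dataclass
class FeaturePacket:
    timestamp: float          # UTC seconds
    device_id: str
    session_id: str
    features: np.ndarray      # includes the FHI
    signature: str = ""       # HMAC-SHA256 hex digest

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float).reshape(-1)

    def payload_bytes(self) -> bytes:
        """Canonical signing payload (sorted-key JSON, fixed float repr)."""
        doc = {
            "ts": round(float(self.timestamp), 6),
            "device": self.device_id,
            "session": self.session_id,
            "features": [round(float(v), 12) for v in self.features],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()

    def to_json(self) -> str:
        doc = json.loads(self.payload_bytes())
        doc["hmac"] = self.signature
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FeaturePacket":
        doc = json.loads(text)
        return cls(timestamp=doc["ts"], device_id=doc["device"],
                   session_id=doc["session"],
                   features=np.asarray(doc["features"], dtype=float),
                   signature=doc.get("hmac", ""))


def sign_packet(packet: FeaturePacket, key: bytes) -> FeaturePacket:
    packet.signature = hmac.new(key, packet.payload_bytes(),
                                hashlib.sha256).hexdigest()
    return packet


@dataclass
class ValidationResult:
    accepted: bool
    reason: str               # "ok" | "unknown_device" | "bad_hmac" |
    #                           "stale" | "malformed"

    def __bool__(self) -> bool:
        return self.accepted


def validate_packet(packet, key: bytes, now: float,
                    known_devices: set[str] | None = None,
                    max_delay: float = MAX_PACKET_DELAY_S
                    ) -> ValidationResult:
    """Total validation: every input yields accept or a categorised reject.

    Check order: device registry -> HMAC integrity -> staleness.  The
    signature check recomputes the HMAC with the pre-shared key and
    compares in constant time.
    """
    if not isinstance(packet, FeaturePacket):
        try:
            packet = FeaturePacket.from_json(packet)
        except Exception:
            return ValidationResult(False, "malformed")
    if not np.all(np.isfinite(packet.features)) or packet.features.size == 0:
        return ValidationResult(False, "malformed")
    if not isinstance(packet.signature, str) or len(packet.signature) != 64:
        return ValidationResult(False, "malformed")
    if known_devices is not None and packet.device_id not in known_devices:
        return ValidationResult(False, "unknown_device")
    expected = hmac.new(key, packet.payload_bytes(),
                        hashlib.sha256).hexdigest()
    if not hmac.compare_digest(expected, packet.signature):
        return ValidationResult(False, "bad_hmac")
    if now - packet.timestamp > max_delay:
        return ValidationResult(False, "stale")
    return ValidationResult(True, "ok")


# --------------------------------------------------------------- risk ----
@dataclass
class RiskScore:
    r: float
    forwarded: bool

    def __post_init__(self):
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("risk must lie in [0, 1]")


class RiskModel:
    """Two-class softmax risk gate: R = softmax(Wx + b)[high]."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=float)    # (2, d): rows (high, low)
        self.b = np.asarray(b, dtype=float)    # (2,)
        if self.W.shape[0] != 2 or self.b.shape != (2,):
            raise ValueError("risk model needs two classes (high, low)")

    @property
    def n_features(self) -> int:
        return self.W.shape[1]

    def logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.size != self.n_features:
            raise ValueError(
                f"feature dimension {x.size} != model {self.n_features}")
        return self.W @ x + self.b

    @classmethod
    def fit_logistic(cls, X: np.ndarray, y_high: np.ndarray) -> "RiskModel":
        """Fit from labelled packets via scikit-learn logistic regression.

        ``y_high`` is 1 for high-risk packets.  The binary coefficient
        vector maps onto the two-class softmax as W = (w, 0), b = (b0, 0).
        """
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(max_iter=1000).fit(np.asarray(X), y_high)
        w = lr.coef_[0]
        b0 = float(lr.intercept_[0])
        return cls(W=np.vstack([w, np.zeros_like(w)]), b=np.array([b0, 0.0]))


def risk_score(x: np.ndarray, model: RiskModel,
               threshold: float = FORWARD_THRESHOLD) -> RiskScore:
    """High-risk softmax component; forwarded iff R > threshold (strict)."""
    z = model.logits(x)
    z = z - z.max()
    e = np.exp(z)
    r = float(e[0] / e.sum())
    return RiskScore(r=r, forwarded=r > threshold)


# -------------------------------------------------------------- fusion ---
STRUCT_DIM = 64
FHV_DIM = 2


@dataclass
class FusedState:
    z: np.ndarray
    structural_embedding: np.ndarray
    fhv: np.ndarray
    composite_risk: float | None = None
    stale_pairing: bool = False


class FusionMLP(nn.Module):
    """Shallow fusion MLP: concat(S, FHV) -> 128 ReLU -> 64 ReLU -> 64."""

    def __init__(self, seed: int = 0, struct_dim: int = STRUCT_DIM):
        rng = np.random.default_rng(seed)
        self.struct_dim = struct_dim
        self.fc1 = nn.Linear(struct_dim + FHV_DIM, 128, rng)
        self.fc2 = nn.Linear(128, 64, rng)
        self.out = nn.Linear(64, 64, rng)

    def graph(self, x: Tensor) -> Tensor:
        return self.out(self.fc2(self.fc1(x).relu()).relu())

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.graph(Tensor(np.atleast_2d(x))).data


def fuse(s: np.ndarray, fhv, mlp: FusionMLP,
         stale_pairing: bool = False) -> FusedState:
    """Z(t) = MLP(S || FHV(t)); concatenation order is fixed (S first)."""
    s = np.asarray(s, dtype=float).reshape(-1)
    if s.size != mlp.struct_dim:
        raise ValueError(
            f"structural embedding dim {s.size} != {mlp.struct_dim}")
    fhv_arr = (np.array([fhv.fb, fhv.fhi]) if hasattr(fhv, "fb")
               else np.asarray(fhv, dtype=float).reshape(-1))
    if fhv_arr.size != FHV_DIM:
        raise ValueError("FHV must have exactly 2 components (FB, FHI)")
    x = np.concatenate([s, fhv_arr])
    z = mlp(x)[0]
    return FusedState(z=z, structural_embedding=s, fhv=fhv_arr,
                      stale_pairing=stale_pairing)


class CompositeRiskHead(nn.Module):
    """Single logistic unit on the fused vector Z(t)."""

    def __init__(self, seed: int = 0, dim: int = 64):
        rng = np.random.default_rng(seed)
        self.linear = nn.Linear(dim, 1, rng)

    def graph(self, z: Tensor) -> Tensor:
        return self.linear(z).sigmoid()

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.graph(Tensor(np.atleast_2d(z))).data[:, 0]


def composite_risk(state: FusedState, head: CompositeRiskHead) -> float:
    """Composite risk in (0, 1); monotone in the head's single logit."""
    r = float(head(state.z[None])[0])
    state.composite_risk = r
    return r


def train_composite_risk(pairs: np.ndarray, labels: np.ndarray,
                         mlp: FusionMLP, head: CompositeRiskHead,
                         lr: float = 1e-3, epochs: int = 200) -> dict:
    """Jointly train the fusion MLP and the logistic head.

    ``pairs`` is (n, struct_dim + 2) concatenated (S || FHV) inputs,
    ``labels`` binary high-risk indicators.  Full-batch Adam on binary
    cross-entropy.
    """
    X = Tensor(np.asarray(pairs, dtype=float))
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    params = mlp.parameters() + head.parameters()
    opt = nn.Adam(params, lr=lr)
    history = {"loss": []}
    eps = 1e-12
    for _ in range(epochs):
        opt.zero_grad()
        p = head.graph(mlp.graph(X))
        p_clamped = p * (1 - 2 * eps) + eps
        loss = -(Tensor(y) * p_clamped.log()
                 + Tensor(1 - y) * (1 - p_clamped).log()).mean()
        loss.backward()
        opt.step()
        history["loss"].append(loss.item())
    return history


# ------------------------------------------------------------ alignment --
def align(fhv_times: np.ndarray, scan_times: np.ndarray) -> np.ndarray:
    """Pair each FHV with the latest scan at or before it.

    Returns an index into ``scan_times`` per FHV, or -1 when the FHV
    precedes every scan (held unpaired).  Both inputs must be sorted.
    """
    fhv_times = np.asarray(fhv_times, dtype=float)
    scan_times = np.asarray(scan_times, dtype=float)
    if scan_times.size == 0:
        return np.full(fhv_times.shape, -1, dtype=int)
    idx = np.searchsorted(scan_times, fhv_times, side="right") - 1
    return idx
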