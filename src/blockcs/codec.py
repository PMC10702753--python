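"""Whole-image block-CS encode/decode and the serialized .bcs container.

The encoder runs, per RGB channel and per 8x8 block: center pixels at zero
(subtract 128), 2-D DCT, column-major vectorization, Gaussian acquisition
Y = A v.  One measurement matrix A, regenerated from the seed stored in the
header, is shared by every block and channel, so the container only carries
the measurement payload.  The decoder inverts the chain with OMP per block
and clips/rounds to 8-bit only at the very end.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.fft import dctn, idctn
from sklearn.base import BaseEstimator

from . import cs_core

__all__ = [
    "CodecConfig",
    "CompressedImage",
    "BlockCSCodec",
    "preprocess",
    "encode_image",
    "decode_image",
    "psnr",
    "write_bcs",
    "read_bcs",
]

PIXEL_CENTER = 128.0
BCS_MAGIC = b"BCS1"
_HEADER = struct.Struct("<4sBIHHqB")  # magic, version, N, B, M, seed, channels


@dataclass
class CodecConfig:
    """Codec parameters.

    ``measurements`` defaults to 4, i.e. a CS ratio of M/L = 4/64 = 6.25%
    (compression ratio 16) at the default 8x8 block.
    """

    resize_to: int = 256
    block_size: int = 8
    measurements: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError(f"block size must be >= 2, got {self.block_size}")
        if self.resize_to % self.block_size != 0:
            raise ValueError(
                f"target side {self.resize_to} is not divisible by "
                f"block size {self.block_size}"
            )
        if not 1 <= self.measurements <= self.block_size**2:
            raise ValueError(
                f"measurements must be in [1, {self.block_size ** 2}], "
                f"got {self.measurements}"
            )

    @property
    def ambient_dim(self) -> int:
        return self.block_size**2

    @property
    def compression_ratio(self) -> float:
        return self.ambient_dim / self.measurements


@dataclass
class CompressedImage:
    """Header plus per-channel, per-block measurement vectors (block order)."""

    resize_to: int
    block_size: int
    measurements: int
    seed: int
    channels: int
    payload: np.ndarray  # (channels, n_blocks, M)

    def __post_init__(self) -> None:
        expected = (self.channels, self.n_blocks, self.measurements)
        if tuple(self.payload.shape) != expected:
            raise ValueError(
                f"payload shape {self.payload.shape} does not match header "
                f"(expected {expected})"
            )

    @property
    def n_blocks(self) -> int:
        return (self.resize_to // self.block_size) ** 2

    @property
    def config(self) -> CodecConfig:
        return CodecConfig(
            resize_to=self.resize_to,
            block_size=self.block_size,
            measurements=self.measurements,
            seed=self.seed,
        )


def _load_rgb(image) -> np.ndarray:
    """Accept a path, PIL image or array; return (H, W, 3) uint8."""
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:  # grayscale: replicate to three planes
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return image[:, :, :3].astype(np.uint8)


def preprocess(image, config: CodecConfig) -> np.ndarray:
    """Read and bilinear-resize an image to three N x N float planes.

    Returns an array of shape (3, N, N) with values in [0, 255].
    Grayscale inputs are replicated across the three planes.
    """
    arr = _load_rgb(image)
    n = config.resize_to
    if arr.shape[:2] != (n, n):
        arr = np.asarray(
            Image.fromarray(arr).resize((n, n), Image.BILINEAR)
        )
    return arr.transpose(2, 0, 1).astype(float)


def _plane_to_vectors(plane: np.ndarray, b: int) -> np.ndarray:
    """Center, tile into blocks, DCT and vectorize: (n_blocks, B**2)."""
    n = plane.shape[0]
    blocks = (
        (plane - PIXEL_CENTER)
        .reshape(n // b, b, n // b, b)
        .swapaxes(1, 2)
        .reshape(-1, b, b)
    )
    coeffs = dctn(blocks, type=2, norm="ortho", axes=(1, 2))
    # column-major vectorization of each block: (r, c) -> c*B + r
    return coeffs.transpose(0, 2, 1).reshape(-1, b * b)


def _vectors_to_plane(vectors: np.ndarray, n: int, b: int) -> np.ndarray:
    """Inverse of :func:`_plane_to_vectors` (no clipping)."""
    coeffs = vectors.reshape(-1, b, b).transpose(0, 2, 1)
    blocks = idctn(coeffs, type=2, norm="ortho", axes=(1, 2)) + PIXEL_CENTER
    return (
        blocks.reshape(n // b, n // b, b, b)
        .swapaxes(1, 2)
        .reshape(n, n)
    )


class BlockCSCodec(BaseEstimator):
    """Block-based compressive-sensing image codec.

    Parameters mirror :class:`CodecConfig`; the estimator is stateless
    (nothing is fitted) and exposes :meth:`encode` / :meth:`decode`.

    Examples
    --------
    >>> codec = BlockCSCodec(resize_to=64, measurements=32, seed=7)
    >>> compressed = codec.encode(rgb_array)          # doctest: +SKIP
    >>> reconstruction = codec.decode(compressed)     # doctest: +SKIP
    """

    def __init__(
        self,
        resize_to: int = 256,
        block_size: int = 8,
        measurements: int = 4,
        seed: int = 0,
    ) -> None:
        self.resize_to = resize_to
        self.block_size = block_size
        self.measurements = measurements
        self.seed = seed

    @property
    def config(self) -> CodecConfig:
        return CodecConfig(
            resize_to=self.resize_to,
            block_size=self.block_size,
            measurements=self.measurements,
            seed=self.seed,
        )

    def encode(self, image) -> CompressedImage:
        cfg = self.config
        planes = preprocess(image, cfg)
        a = cs_core.make_measurement_matrix(
            cfg.measurements, cfg.ambient_dim, cfg.seed
        )
        payload = np.stack(
            [_plane_to_vectors(p, cfg.block_size) @ a.T for p in planes]
        )
        return CompressedImage(
            resize_to=cfg.resize_to,
            block_size=cfg.block_size,
            measurements=cfg.measurements,
            seed=cfg.seed,
            channels=payload.shape[0],
            payload=payload,
        )

    def decode(self, compressed: CompressedImage) -> np.ndarray:
        """Reconstruct an (N, N, 3) uint8 image from measurements."""
        cfg = compressed.config
        a = cs_core.make_measurement_matrix(
            cfg.measurements, cfg.ambient_dim, cfg.seed
        )
        n, b = cfg.resize_to, cfg.block_size
        planes = []
        for channel in compressed.payload:
            vectors = np.empty((channel.shape[0], cfg.ambient_dim))
            for i, y in enumerate(channel):
                vectors[i] = cs_core.omp_reconstruct(a, y).estimate
            planes.append(_vectors_to_plane(vectors, n, b))
        out = np.stack(planes, axis=-1)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    # transformer-style aliases so the codec drops into sklearn pipelines
    def fit(self, X=None, y=None) -> "BlockCSCodec":
        return self

    def transform(self, images) -> list[CompressedImage]:
        return [self.encode(img) for img in images]

    def inverse_transform(self, compressed) -> list[np.ndarray]:
        return [self.decode(c) for c in compressed]


def encode_image(image, config: CodecConfig) -> CompressedImage:
    """Encode one image under ``config`` (steps: resize through acquisition)."""
    return BlockCSCodec(**_cfg_kwargs(config)).encode(image)


def decode_image(compressed: CompressedImage) -> np.ndarray:
    """Decode a compressed image back to an (N, N, 3) uint8 array."""
    return BlockCSCodec(**_cfg_kwargs(compressed.config)).decode(compressed)


def _cfg_kwargs(config: CodecConfig) -> dict:
    return dict(
        resize_to=config.resize_to,
        block_size=config.block_size,
        measurements=config.measurements,
        seed=config.seed,
    )


def psnr(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for 8-bit data (inf if identical)."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise ValueError(
            f"shape mismatch: {original.shape} vs {reconstructed.shape}"
        )
    mse = float(np.mean((original - reconstructed) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def write_bcs(compressed: CompressedImage, path) -> None:
    """Write the single-file .bcs container (header + float64 LE payload)."""
    header = _HEADER.pack(
        BCS_MAGIC,
        1,
        compressed.resize_to,
        compressed.block_size,
        compressed.measurements,
        compressed.seed,
        compressed.channels,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(compressed.payload.astype("<f8").tobytes())


def read_bcs(path) -> CompressedImage:
    """Read a .bcs container; raises ValueError on a corrupted file."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size or raw[:4] != BCS_MAGIC:
        raise ValueError(f"{path}: not a .bcs container")
    magic, version, n, b, m, seed, channels = _HEADER.unpack_from(raw)
    if version != 1:
        raise ValueError(f"{path}: unsupported container version {version}")
    n_blocks = (n // b) ** 2
    expected = channels * n_blocks * m
    body = np.frombuffer(raw, dtype="<f8", offset=_HEADER.size)
    if body.size != expected:
        raise ValueError(
            f"{path}: payload has {body.size} values, header implies {expected}"
        )
    return CompressedImage(
        resize_to=n,
        block_size=b,
        measurements=m,
        seed=seed,
        channels=channels,
        payload=body.reshape(channels, n_blocks, m).copy(),
    )


def roundtrip_psnr(image, config: CodecConfig) -> float:
    """PSNR between the preprocessed input and its encode/decode round trip."""
    planes = preprocess(image, config)
    reference = np.clip(np.rint(planes.transpose(1, 2, 0)), 0, 255)
    recon = decode_image(encode_image(image, config))
    value = psnr(reference, recon)
    if np.isinf(value):
        warnings.warn("identical images: PSNR is unbounded", stacklevel=2)
    return value
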