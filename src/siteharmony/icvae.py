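"""Invariant conditional VAE (ICVAE) harmonization.

An encoder compresses each subject's (standardized) feature block into a
low-dimensional latent vector Z; the decoder reconstructs the block from Z
concatenated with a site one-hot code; an adversarial site classifier on the
reconstructions pushes site information out of them.  Harmonization decodes
every subject with the *target* site's one-hot, unifying the site condition.

Per training step the generator (encoder+decoder) minimizes

    L = L_recon + alpha * L_marginal + beta * L_prior - gamma * L_adv

with alpha=1, beta=0.1, gamma=10: mean-squared reconstruction error, an RBF
MMD between the batch of encoder posterior samples and fresh draws from the
decoder's generative latent marginal N(0, I), the analytic Gaussian KL to the
standard-normal prior, and the adversary's softmax cross-entropy (the
adversary itself is trained in alternating steps to minimize that same
cross-entropy; the minus sign makes the generator confuse it).  All layers
use tanh except the adversary's softmax output.

Feature matrices wider than 512 columns are split into 512-wide blocks, the
last block zero-padded; each block trains its own network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Linear, Tensor, concat, cross_entropy, rbf_mmd2
from .core import FeatureMatrix, HarmonizationError, ValidatedDemographics

BLOCK_SIZE = 512


@dataclass
class ICVAEConfig:
    input_dim: int = BLOCK_SIZE
    encoder_hidden: tuple = (256, 128, 64)
    latent_dim: int = 64
    adversary_hidden: tuple = (32, 32)
    alpha: float = 1.0
    beta: float = 0.1
    gamma: float = 10.0
    epochs: int = 200
    learning_rate: float = 1e-3
    #: small batches give the generator enough updates per epoch on
    #: desk-scale cohorts (a few hundred subjects)
    batch_size: int = 16
    #: adversary updates per generator update
    adversary_steps: int = 1
    adversary_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise HarmonizationError("loss weights alpha, beta, gamma must be > 0")


@dataclass
class ICVAELossBreakdown:
    """Per-epoch loss components; L_total always equals the printed
    combination L_recon + alpha*L_marginal + beta*L_prior - gamma*L_adv."""

    L_recon: list = field(default_factory=list)
    L_marginal: list = field(default_factory=list)
    L_prior: list = field(default_factory=list)
    L_adv: list = field(default_factory=list)
    L_total: list = field(default_factory=list)


def chunk_features(matrix: FeatureMatrix, block: int = BLOCK_SIZE):
    """Split columns into `block`-wide chunks, zero-padding the last.

    Returns (list of (n, block) arrays, list of true widths).
    """
    values = matrix.values
    p = values.shape[1]
    blocks, widths = [], []
    for start in range(0, p, block):
        chunk = values[:, start:start + block]
        width = chunk.shape[1]
        if width < block:
            chunk = np.pad(chunk, ((0, 0), (0, block - width)))
        blocks.append(chunk)
        widths.append(width)
    return blocks, widths


class _BlockModel:
    """Encoder/decoder/adversary for one 512-feature block."""

    def __init__(self, config: ICVAEConfig, n_site: int, rng: np.random.Generator):
        c = config
        self.config = c
        self.n_site = n_site
        dims = [c.input_dim, *c.encoder_hidden]
        self.enc = [Linear(a, b, rng) for a, b in zip(dims, dims[1:])]
        self.enc_mu = Linear(dims[-1], c.latent_dim, rng)
        self.enc_logvar = Linear(dims[-1], c.latent_dim, rng)
        ddims = [c.latent_dim + n_site, *reversed(c.encoder_hidden), c.input_dim]
        self.dec = [Linear(a, b, rng) for a, b in zip(ddims, ddims[1:])]
        adims = [c.input_dim, *c.adversary_hidden, n_site]
        self.adv = [Linear(a, b, rng) for a, b in zip(adims, adims[1:])]
        # per-feature standardization, fitted on the training block
        self.mu_x = None
        self.sd_x = None

    @property
    def gen_params(self):
        layers = self.enc + [self.enc_mu, self.enc_logvar] + self.dec
        return [p for layer in layers for p in layer.params]

    @property
    def adv_params(self):
        return [p for layer in self.adv for p in layer.params]

    def encode(self, x: Tensor):
        h = x
        for layer in self.enc:
            h = layer(h).tanh()
        return self.enc_mu(h), self.enc_logvar(h)

    def decode(self, z: Tensor, onehot: np.ndarray) -> Tensor:
        h = concat([z, Tensor(onehot)], axis=1)
        for layer in self.dec[:-1]:
            h = layer(h).tanh()
        return self.dec[-1](h)

    def adversary_logits(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.adv[:-1]:
            h = layer(h).tanh()
        return self.adv[-1](h)

    def state(self):
        layers = self.enc + [self.enc_mu, self.enc_logvar] + self.dec + self.adv
        params = {}
        for i, layer in enumerate(layers):
            params[f"W{i}"] = layer.W.data
            params[f"b{i}"] = layer.b.data
        params["mu_x"] = self.mu_x
        params["sd_x"] = self.sd_x
        return params


def _kl_to_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """Mean over the batch of KL(N(mu, diag(exp(logvar))) || N(0, I))."""
    term = (logvar.exp() + mu * mu - logvar - 1.0).sum(axis=1) * 0.5
    return term.mean()


def _latent_bandwidth(z: np.ndarray, prior: np.ndarray) -> float:
    pooled = np.vstack([z, prior])
    d2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(pooled.shape[0], k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def train_icvae(matrix: FeatureMatrix, demographics: ValidatedDemographics,
                config: ICVAEConfig, workers: int = 0):
    """Train one network per 512-feature block.

    Returns (models, traces): per-block :class:`_BlockModel` and
    :class:`ICVAELossBreakdown`.  Training is reproducible from the seed.
    """
    if len(demographics.site_order) < 2:
        raise HarmonizationError("ICVAE requires at least 2 sites")
    blocks, widths = chunk_features(matrix)
    codes = demographics.site_codes()
    n_site = len(demographics.site_order)
    onehot = np.eye(n_site)[codes]
    models, traces = [], []
    for bi, block in enumerate(blocks):
        model, trace = _train_block(block, codes, onehot, n_site, config,
                                    seed=config.seed + 7919 * bi)
        models.append(model)
        traces.append(trace)
    return models, traces


def _train_block(block: np.ndarray, codes: np.ndarray, onehot: np.ndarray,
                 n_site: int, config: ICVAEConfig, seed: int):
    n = block.shape[0]
    rng = np.random.default_rng(seed)
    model = _BlockModel(config, n_site, rng)
    model.mu_x = block.mean(axis=0)
    sd = block.std(axis=0)
    model.sd_x = np.where(sd > 0, sd, 1.0)  # padded columns are constant 0
    X = (block - model.mu_x) / model.sd_x

    batch_size = min(config.batch_size, n)
    gen_opt = Adam(model.gen_params, lr=config.learning_rate)
    adv_opt = Adam(model.adv_params, lr=config.adversary_lr)
    trace = ICVAELossBreakdown()

    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        ep = dict(L_recon=[], L_marginal=[], L_prior=[], L_adv=[], L_total=[])
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb = X[idx]
            yb = codes[idx]
            hb = onehot[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            prior = rng.standard_normal((len(idx), config.latent_dim))
            # the adversarial game plays on reconstructions decoded with a
            # *random* site code: the decoder cannot hide the source site by
            # cancelling it against the conditioning one-hot, so the pressure
            # lands on the latent representation itself
            h_rand = np.eye(n_site)[rng.integers(n_site, size=len(idx))]

            # --- adversary steps: minimize CE on detached reconstructions
            x_in = Tensor(xb)
            mu, logvar = model.encode(x_in)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
            recon_rand_detached = model.decode(z, h_rand).detach()
            for _ in range(config.adversary_steps):
                adv_opt.zero_grad()
                adv_loss = cross_entropy(
                    model.adversary_logits(recon_rand_detached), yb)
                adv_loss.backward()
                adv_opt.step()

            # --- generator step: full objective, adversary frozen
            mu, logvar = model.encode(x_in)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
            recon = model.decode(z, hb)
            # squared Euclidean distance input<->output, averaged over the batch
            l_recon = ((recon - Tensor(xb)) ** 2.0).sum(axis=1).mean()
            h = _latent_bandwidth(z.data, prior)
            l_marginal = rbf_mmd2(z, Tensor(prior), h)
            l_prior = _kl_to_standard_normal(mu, logvar)
            recon_rand = model.decode(z, h_rand)
            l_adv = cross_entropy(model.adversary_logits(recon_rand), yb)
            total = (l_recon + config.alpha * l_marginal
                     + config.beta * l_prior - config.gamma * l_adv)
            gen_opt.zero_grad()
            adv_opt.zero_grad()          # adversary params receive grads but stay frozen
            total.backward()
            gen_opt.step()

            ep["L_recon"].append(float(l_recon.data))
            ep["L_marginal"].append(float(l_marginal.data))
            ep["L_prior"].append(float(l_prior.data))
            ep["L_adv"].append(float(l_adv.data))
            ep["L_total"].append(float(total.data))
        for key, vals in ep.items():
            getattr(trace, key).append(float(np.mean(vals)))
        if not np.isfinite(trace.L_total[-1]):
            raise HarmonizationError(
                f"ICVAE training diverged at epoch {_epoch}; loss trace: "
                f"{trace.L_total[-5:]}")
    return model, trace


def icvae_harmonize(models, matrix: FeatureMatrix,
                    demographics: ValidatedDemographics, target_site: str,
                    seed: int | None = None) -> FeatureMatrix:
    """Decode every subject with the target site's one-hot.

    Encoding uses the posterior mean (no sampling), so the output is
    deterministic given the trained model.
    """
    if target_site not in demographics.site_order:
        raise HarmonizationError(
            f"target site {target_site!r} was not among the training sites")
    blocks, widths = chunk_features(matrix)
    if len(blocks) != len(models):
        raise HarmonizationError(
            f"matrix has {len(blocks)} feature blocks but the model was "
            f"trained on {len(models)}")
    n_site = len(demographics.site_order)
    tgt_idx = demographics.site_order.index(target_site)
    onehot = np.zeros((matrix.n_subjects, n_site))
    onehot[:, tgt_idx] = 1.0
    out_cols = []
    for model, block, width in zip(models, blocks, widths):
        X = (block - model.mu_x) / model.sd_x
        mu, _ = model.encode(Tensor(X))
        recon = model.decode(mu, onehot)
        values = recon.data * model.sd_x + model.mu_x
        out_cols.append(values[:, :width])  # padded columns never leak out
    return matrix.with_values(np.hstack(out_cols))


def adversary_accuracy(model: "_BlockModel", block: np.ndarray,
                       codes: np.ndarray, onehot: np.ndarray) -> float:
    """Adversary accuracy on reconstructions (posterior-mean encodings)."""
    X = (block - model.mu_x) / model.sd_x
    mu, _ = model.encode(Tensor(X))
    recon = model.decode(mu, onehot)
    logits = model.adversary_logits(recon).data
    return float((logits.argmax(axis=1) == codes).mean())


def save_params(models, out_dir: str):
    """Write per-block network parameters under `out_dir`/params."""
    params_dir = os.path.join(out_dir, "params")
    os.makedirs(params_dir, exist_ok=True)
    paths = []
    for bi, model in enumerate(models):
        path = os.path.join(params_dir, f"block_{bi:03d}.npz")
        np.savez(path, **model.state())
        paths.append(path)
    return paths
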