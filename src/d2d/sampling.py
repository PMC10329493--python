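"""Generate novel target-domain sequences conditioned on a source sequence.

Unlike the teacher-forced regularizer used during training, generation is
ancestral: each position is conditioned on the previously *sampled* symbols.
Families are fixed-length alignments, so decoding always runs for exactly
Nout steps and special tokens are masked out of the candidate set (gaps are
ordinary residues and remain sampleable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pmsa import PairedMSA


@dataclass
class SampleRequest:
    mode: str = "temperature"       # greedy | temperature | top_k
    temperature: float = 1.0
    top_k: int = 5
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("greedy", "temperature", "top_k"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mode == "top_k" and self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def sample_target(model, source_seq, Nout: int, req: SampleRequest):
    """Sample ``req.n_samples`` target sequences of length Nout given a source.

    Returns ``(sequences, logliks)``: decoded strings and their conditional
    log-likelihoods under the model (sum of the chosen symbols' model
    log-probabilities).  Greedy mode is deterministic and ignores the seed.
    """
    tok = model.tokenizer
    src = np.asarray(tok.encode(source_seq) if isinstance(source_seq, str)
                     else source_seq, dtype=np.int64)
    n = req.n_samples
    rng = np.random.default_rng(req.seed)
    src_b = np.repeat(src[None, :], n, axis=0)
    prefix = np.full((n, 1), tok.sos_id, dtype=np.int64)
    logliks = np.zeros(n)
    for _ in range(Nout):
        rows = model.next_logprobs(src_b, prefix)[:, -1, :]     # (n, V)
        res = rows[:, : tok.n_residues]                          # mask specials
        if req.mode == "greedy":
            choice = res.argmax(axis=1)
        else:
            logits = res / req.temperature
            if req.mode == "top_k":
                k = min(req.top_k, tok.n_residues)
                thresh = np.sort(logits, axis=1)[:, -k][:, None]
                logits = np.where(logits >= thresh, logits, -np.inf)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            choice = (p.cumsum(axis=1) < u).sum(axis=1).clip(max=tok.n_residues - 1)
        logliks += res[np.arange(n), choice]
        prefix = np.concatenate([prefix, choice[:, None]], axis=1)
    seqs = [tok.decode(row) for row in prefix[:, 1:]]
    return seqs, logliks


def export_augmented_pmsa(model, pmsa_train: PairedMSA, samples_per_input: int = 8,
                          seed: int = 0, temperature: float = 1.0,
                          mode: str = "temperature",
                          collapse_duplicates: bool = False) -> PairedMSA:
    """Pair each natural source with sampled targets for downstream coupling
    analysis (e.g. DCA contact inference on the augmented alignment).

    Output ids carry provenance: source id, sample index, log-likelihood,
    temperature and seed.  ``collapse_duplicates`` keeps one row per distinct
    sampled target per input (greedy sampling then yields M_out = M_in).
    """
    if samples_per_input < 1:
        raise ValueError("samples_per_input must be >= 1")
    sources, targets, ids = [], [], []
    for r, (sid, src) in enumerate(zip(pmsa_train.ids, pmsa_train.source_seqs)):
        req = SampleRequest(mode=mode, temperature=temperature,
                            n_samples=samples_per_input, seed=seed + 7919 * r)
        seqs, lls = sample_target(model, src, pmsa_train.Nout, req)
        seen = set()
        for k, (s, ll) in enumerate(zip(seqs, lls)):
            if collapse_duplicates and s in seen:
                continue
            seen.add(s)
            sources.append(src)
            targets.append(s)
            ids.append(f"{sid}|sample{k}|ll={ll:.3f}|T={temperature}|seed={seed}")
    return PairedMSA(sources, targets, ids)
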