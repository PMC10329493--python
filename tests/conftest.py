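import numpy as np
import pytest

from d2d.alphabet import Tokenizer
from d2d.models import ModelConfig, TransformerModel
from d2d.pmsa import PairedMSA


@pytest.fixture(scope="session")
def tok():
    return Tokenizer()


@pytest.fixture()
def tiny_pmsa():
    return PairedMSA(
        source_seqs=["ACDEF", "GHIKL", "MNP-R"],
        target_seqs=["WYVA", "C-DE", "FGHI"],
        ids=["a", "b", "c"],
    )


@pytest.fixture()
def tiny_model(tok):
    """Small float64 Transformer for exact numeric checks."""
    cfg = ModelConfig(n_layers=1, n_heads=1, d_model=8, d_ff=16,
                      dropout=0.0, dtype="float64")
    return TransformerModel(cfg, tok, seed=0)


class TableModel:
    """Evaluation stub with hand-specified residue conditionals.

    ``table`` maps (target row index) -> (Nout, 21) log-probability rows; a
    single (Nout, 21) array is broadcast to every row.  Used to pin metric
    values without training.
    """

    def __init__(self, tokenizer, logprob_rows):
        self.tokenizer = tokenizer
        self._rows = np.asarray(logprob_rows)

    def conditional_logprobs(self, src_tokens, tgt_tokens):
        tgt_tokens = np.atleast_2d(tgt_tokens)
        B = tgt_tokens.shape[0]
        if self._rows.ndim == 2:
            return np.broadcast_to(self._rows, (B,) + self._rows.shape).copy()
        return self._rows[:B]


@pytest.fixture()
def table_model_factory(tok):
    def make(logprob_rows):
        return TableModel(tok, logprob_rows)
    return make


def perfect_model_for(tok, pmsa, eps=1e-12):
    """Stub assigning probability ~1 to each true target symbol."""

    class Perfect:
        tokenizer = tok

        def conditional_logprobs(self, src_tokens, tgt_tokens):
            tgt_tokens = np.atleast_2d(tgt_tokens)
            B, Nout = tgt_tokens.shape
            out = np.full((B, Nout, tok.n_residues), np.log(eps))
            np.put_along_axis(out, tgt_tokens[..., None], np.log(1.0 - eps), axis=-1)
            return out

    return Perfect()
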