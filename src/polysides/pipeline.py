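"""Run configuration and stage wiring: prepare -> embed -> fuse -> train -> evaluate.

Every CLI subcommand calls one of these library functions with the same
config object, so scripted runs and shell runs are interchangeable. A run
writes a manifest recording input hashes, derived seeds and output paths;
re-running with the same config and inputs reproduces the deterministic
stages byte-for-byte.

One global seed fans out to per-stage seeds through a stable derivation
(blake2 of ``"<seed>:<stage>"``), so a stage can be rerun in isolation with
the seed it saw inside the full pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataprep, encoders, gnn, metrics, mlp, synth

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little") % (2**31)


@dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    # dataprep
    associations_path: str | None = None
    chemistry_path: str | None = None
    min_pairs: int = 1  # the real-data CLI default is 500; simulated runs keep all
    # encoders
    provider: str = "hash-ngram"
    dim: int = 128
    max_len: int = 64
    fusion: str = "sum"
    # simulate
    n_drugs: int = 80
    n_side_effects: int = 25
    latent_dim: int = 8
    n_pairs: int = 400
    noise_sd: float = 0.1
    # classifiers
    mlp: dict = field(default_factory=dict)
    gnn: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "RunConfig":
        """Build a config, reporting every invalid field at once."""
        known = {f for f in cls.__dataclass_fields__}
        problems = [f"unknown config field {k!r}" for k in raw if k not in known]
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if cfg.fusion not in encoders.FUSION_STRATEGIES:
            problems.append(
                f"fusion must be one of {encoders.FUSION_STRATEGIES}, got {cfg.fusion!r}"
            )
        if cfg.provider not in encoders.available_providers():
            problems.append(f"unknown provider {cfg.provider!r}")
        if cfg.min_pairs < 1:
            problems.append("min_pairs must be >= 1")
        if problems:
            raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
        return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    def __init__(self, config: RunConfig):
        self.data = {"config": asdict(config), "inputs": {}, "outputs": {}, "seeds": {}}

    def record_input(self, name: str, path: Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _hash_file(path)}

    def record_output(self, name: str, path: Path) -> None:
        self.data["outputs"][name] = {"path": str(path), "sha256": _hash_file(path)}

    def record_seed(self, stage: str, seed: int) -> None:
        self.data["seeds"][stage] = seed

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def simulate(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    """Write a synthetic association + chemistry table in the dataprep formats."""
    out_dir.mkdir(parents=True, exist_ok=True)
    model = synth.PlantedModel(
        n_drugs=config.n_drugs,
        n_side_effects=config.n_side_effects,
        latent_dim=config.latent_dim,
        noise_sd=config.noise_sd,
        seed=derive_seed(config.seed, "simulate"),
    )
    ds = synth.gen_associations(model, config.n_pairs)
    import pandas as pd

    assoc = pd.DataFrame(
        {
            "STITCH 1": [r.drug_a for r in ds.associations],
            "STITCH 2": [r.drug_b for r in ds.associations],
            "Polypharmacy Side Effect": [r.side_effect_id for r in ds.associations],
            "Side Effect Name": [r.side_effect_name for r in ds.associations],
        }
    )
    assoc_path = out_dir / "associations.csv"
    assoc.to_csv(assoc_path, index=False)
    chem_path = out_dir / "chemistry.csv"
    dataprep._write_chem_csv(chem_path, {d.drug_id: d.smiles for d in ds.drugs})
    return {"associations": assoc_path, "chemistry": chem_path}


def prepare(
    config: RunConfig, out_dir: Path, associations_path: Path, chemistry_path: Path | None
) -> dict:
    """Load, filter and group the association table; write table + vocabulary."""
    out_dir.mkdir(parents=True, exist_ok=True)
    records = dataprep.load_association_table(associations_path)
    raw_summary = dataprep.association_summary(records)
    filtered, vocab = dataprep.filter_common_side_effects(records, config.min_pairs)
    table = dataprep.group_to_multilabel(filtered, vocab)
    table.to_frame().to_csv(out_dir / "pair_labels.csv", index=False)
    (out_dir / "vocabulary.json").write_text(
        json.dumps({"entries": list(vocab.entries)}, indent=2)
    )
    summary = {
        "raw": raw_summary,
        "filtered": dataprep.association_summary(filtered),
        "n_pair_rows": len(table),
        "vocabulary_size": len(vocab),
    }
    if chemistry_path is not None:
        drug_ids = sorted({d for p in table.pairs for d in p})
        fetched = dataprep.fetch_smiles(drug_ids, chemistry_path)
        audit = dataprep.compute_structure_keys(
            fetched.records, backend=dataprep.fake_structure_backend
        )
        rows = ["drug_id,structure_key"] + [
            f"{r.drug_id},{r.structure_key}" for r in audit.records
        ]
        (out_dir / "structure_keys.csv").write_text("\n".join(rows) + "\n")
        summary["n_drugs"] = len(fetched.records)
        summary["n_missing_smiles"] = len(fetched.missing)
        summary["n_unique_structure_keys"] = audit.n_unique
        summary["smiles_length"] = dataprep.smiles_length_stats(fetched.records)
    (out_dir / "prepare_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def compare_fusion_strategies(
    seed: int = 7,
    noise_sd: float = 0.0,
    n_pairs: int = 400,
    strategies: tuple[str, ...] = encoders.FUSION_STRATEGIES,
) -> dict[str, float]:
    """Downstream micro-AUROC of each pair-fusion strategy on the additive
    planted fixture.

    The planted model generates labels from <u_a + u_b, v_s>, so summation
    is the correctly specified fusion by construction: at zero feature
    noise the expected ordering is sum >= concat ~ mean > product
    (mean carries the same information as sum up to scale; the elementwise
    product destroys the additive sufficient statistic).
    """
    model = synth.PlantedModel(noise_sd=noise_sd, seed=seed)
    table, _, _, ds = synth.gen_multilabel_fixture(model, n_pairs=n_pairs)
    drug_vecs = {d.drug_id: model.drug_latents[i] for i, d in enumerate(ds.drugs)}
    targets = table.multihot
    split = mlp.split_rows(len(table), mlp.SplitSpec(seed=seed))
    out: dict[str, float] = {}
    for strategy in strategies:
        X = encoders.build_pair_matrix(table, drug_vecs, strategy)
        cfg = mlp.toy_config(output_dim=targets.shape[1], seed=seed)
        m = mlp.build_mlp(cfg, X.shape[1])
        m, _ = mlp.train_mlp(m, X, targets, split, cfg)
        probs = mlp.predict_mlp(m, X[split.test])
        rep = metrics.columnwise_report(probs, targets[split.test])
        out[strategy] = rep.micro["auroc"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (if no input given), prepare, embed, fuse, train both
    classifiers and evaluate; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)

    if config.associations_path is None:
        paths = simulate(config, out / "sim")
        assoc_path, chem_path = paths["associations"], paths["chemistry"]
    else:
        assoc_path = Path(config.associations_path)
        chem_path = Path(config.chemistry_path) if config.chemistry_path else None
    manifest.record_input("associations", assoc_path)
    if chem_path:
        manifest.record_input("chemistry", chem_path)

    prep = prepare(config, out / "prep", assoc_path, chem_path)

    records = dataprep.load_association_table(assoc_path)
    filtered, vocab = dataprep.filter_common_side_effects(records, config.min_pairs)
    table = dataprep.group_to_multilabel(filtered, vocab)

    enc_seed = derive_seed(config.seed, "embed")
    provider = encoders.get_provider(
        config.provider,
        **({"dim": config.dim, "max_len": config.max_len, "seed": enc_seed}
           if config.provider == "hash-ngram"
           else {"max_len": config.max_len}),
    )
    drug_ids = sorted({d for p in table.pairs for d in p})
    fetched = dataprep.fetch_smiles(drug_ids, chem_path) if chem_path else None
    drug_vecs = encoders.embed_drugs(fetched.records, provider)
    pair_matrix = encoders.build_pair_matrix(table, drug_vecs, config.fusion)
    se_matrix = encoders.encode_side_effect_names(vocab.names, provider)
    manifest.record_seed("embed", enc_seed)

    # MLP branch
    mlp_seed = derive_seed(config.seed, "mlp")
    mlp_cfg = mlp.MLPConfig(
        output_dim=len(vocab), seed=mlp_seed, **config.mlp
    )
    split = mlp.split_rows(len(table), mlp.SplitSpec(seed=mlp_seed))
    targets = table.multihot
    model = mlp.build_mlp(mlp_cfg, pair_matrix.shape[1])
    model, mlp_log = mlp.train_mlp(model, pair_matrix, targets, split, mlp_cfg)
    probs = mlp.predict_mlp(model, pair_matrix[split.test])
    mlp_report = metrics.columnwise_report(
        probs, targets[split.test], group_ids=vocab.ids, group_names=vocab.names
    )
    manifest.record_seed("mlp", mlp_seed)

    # GNN branch
    gnn_seed = derive_seed(config.seed, "gnn")
    graph = gnn.build_graph(table, pair_matrix, se_matrix)
    esplit = gnn.split_edges(graph, seed=gnn_seed)
    gnn_cfg = gnn.GNNConfig(seed=gnn_seed, **config.gnn)
    gmodel, gnn_log = gnn.train_gnn(graph, esplit, gnn_cfg)
    test_msg = np.vstack([esplit.train, esplit.val])
    pos_logits = gnn.predict_links(gmodel, graph, esplit.test, test_msg)
    neg_logits = gnn.predict_links(gmodel, graph, esplit.test_negatives, test_msg)
    scored = metrics.ScoredLabels(
        np.concatenate([pos_logits, neg_logits]),
        np.concatenate([np.ones(len(pos_logits)), np.zeros(len(neg_logits))]),
    )
    gnn_summary = {
        "auroc": metrics.auroc(scored),
        "auprc": metrics.auprc(scored),
        "ap50": metrics.ap_at_50(scored),
    }
    manifest.record_seed("gnn", gnn_seed)

    report = {
        "prepare": prep,
        "mlp": {"micro": mlp_report.micro, "macro": mlp_report.macro,
                "epochs": len(mlp_log)},
        "gnn": {**gnn_summary, "epochs": len(gnn_log)},
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    manifest.record_output("report", report_path)
    manifest.write(out / "manifest.json")
    return manifest.data
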