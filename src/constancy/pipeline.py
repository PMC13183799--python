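"""End-to-end orchestration of the two cue-silencing experiments.

Experiment 1 crosses two scene palettes with five illuminants and five
conditions (baseline plus four silenced cues) for every agent: synthetic
human observers (selection trials scaled with MLDS), the trained
reflectance net, the classical estimators, and two analytic anchors — an
oracle that reads ground-truth reflectance (perfect constancy) and a
tristimulus agent that reads the raw image (zero constancy). Experiment 2
crosses four colored surrounds with a per-surround baseline and the
local-surround silencing, labeling illuminants Neighboring or Opposing
relative to each surround.

Synthetic human observers are generated from condition-level true CCI
values (baseline level plus mechanism-specific decrements, individual
offsets and per-condition jitter), then pushed through the full
trial-simulation -> choice-matrix -> MLDS pipeline, so the human numbers
inherit the scaling method's estimation noise exactly as real data would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import agreement as agr
from . import algorithms as alg
from . import colorspace as cs
from . import matching as mm
from . import reflectance as rf
from . import scaling as sca
from . import scenes as sc

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "make_image_agents",
    "train_reflectance_model",
    "simulate_human_cci_exp1",
    "run_experiment1",
    "run_experiment2",
    "make_report",
]

CLASSICAL_METHODS = ("grayworld", "whitepatch", "shadesofgray", "grayedge",
                     "weightedgrayedge")


@dataclass
class ExperimentConfig:
    """Everything that determines a run; the seed pins all randomness."""

    seed: int = 0
    palettes: tuple = ("indoor", "outdoor")
    size: int = 64
    n_locations: int = 5
    axis_offset: float = sc.DEFAULT_AXIS_OFFSET
    target_reflectance: float = sc.DEFAULT_TARGET_REFLECTANCE
    mechanisms: tuple = sc.MECHANISMS
    surrounds: tuple = ("khaki", "rose", "purple", "teal")

    # Human simulation (condition-level true CCI in percent).
    n_participants_exp1: int = 10
    n_participants_exp2: int = 16
    trials_per_illuminant: int = 150
    mlds_restarts: int = 10
    baseline_cci: dict = field(default_factory=lambda: {"indoor": 85.0, "outdoor": 78.0})
    #: Mechanism decrements per scene, mirroring the published human pattern.
    human_delta: dict = field(default_factory=lambda: {
        "indoor": {"local_surround": -23.8, "maximum_flux": -8.0,
                   "spatial_mean_add": -23.3, "spatial_mean_change": -75.7},
        "outdoor": {"local_surround": -14.4, "maximum_flux": -1.4,
                    "spatial_mean_add": -13.6, "spatial_mean_change": -72.9},
    })
    #: Surround-silencing decrements by direction (Experiment 2).
    direction_delta: dict = field(default_factory=lambda: {
        "indoor": {"Neighboring": -2.0, "Opposing": -15.0},
        "outdoor": {"Neighboring": -8.0, "Opposing": -25.0},
    })
    participant_sd: float = 8.0
    condition_sd: float = 6.0

    # Reflectance-net training.
    net_width: int = 16
    pretrain_layouts: int = 15
    pretrain_epochs: int = 30
    finetune_layouts: int = 6
    finetune_epochs: int = 8
    learning_rate: float = 3e-3

    def illuminants(self) -> dict:
        return sc.make_illuminant_set(self.axis_offset)


def _child_seed(rng) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Image agents
# ---------------------------------------------------------------------------

def make_image_agents(config: ExperimentConfig, model=None) -> dict:
    """Agents mapping a rendered scene to a predicted Lab reflectance map.

    Classical estimators run their estimate + von Kries correction per
    capture; the corrected image is re-rendered under the neutral gain into
    the competitor frame, exactly as the learned model's output is scored.
    """
    gn = config.illuminants()["neutral"].gain
    agents = {
        "oracle": lambda s: cs.linear_rgb_to_lab(s.reflectance * gn),
        "tristimulus": lambda s: cs.linear_rgb_to_lab(s.rgb),
    }
    for name in CLASSICAL_METHODS:
        est_fn = alg.ESTIMATORS[name]

        def agent(s, est_fn=est_fn):
            est = est_fn(s.rgb)
            corrected = alg.white_balance(s.rgb, est)
            return cs.linear_rgb_to_lab(np.clip(corrected, 0.0, None) * gn)

        agents[name] = agent
    if model is not None:
        agents["model"] = lambda s: rf.predict(model, s.rgb)
    return agents


def _training_pairs(config, layout_seeds, rng, achromatic_only=False):
    ills = config.illuminants()
    gn = ills["neutral"].gain
    pairs = []
    for s in layout_seeds:
        spec = sc.make_scene_spec(palette=rng.choice(config.palettes), size=config.size,
                                  n_locations=config.n_locations, seed=int(s))
        for ill in ills.values():
            comp = sc.make_competitor_set(config.target_reflectance, ill, ills["neutral"])
            name = "R" if achromatic_only else sc.COMPETITOR_ORDER[rng.integers(0, 5)]
            loc = int(rng.integers(0, config.n_locations))
            sp = replace(spec, target_entries=[(loc, comp.reflectances[name], 1)])
            scene = sc.render(sp, ill, ills["neutral"])
            pairs.append((scene.rgb, cs.linear_rgb_to_lab(scene.reflectance * gn)))
    return pairs


def train_reflectance_model(config: ExperimentConfig) -> tuple:
    """Two-stage protocol: pre-train everything, then decoder-only fine-tune.

    Stage 1 trains all parameters on layouts with varied competitor
    surfaces under all five illuminants; stage 2 freezes the encoder and
    fine-tunes the decoder on baseline scenes containing the achromatic
    reference, mirroring the transfer-learning contract. Returns
    ``(model, loss_trace)``.
    """
    rng = np.random.default_rng(config.seed + 101)
    model = rf.build_model(rf.ReflectanceNetConfig(
        base_width=config.net_width, seed=_child_seed(rng)))
    pre = _training_pairs(config, range(1000, 1000 + config.pretrain_layouts), rng)
    trace = rf.train(model, pre, epochs=config.pretrain_epochs, lr=config.learning_rate,
                     seed=_child_seed(rng), trainable="all")
    fine = _training_pairs(config, range(2000, 2000 + config.finetune_layouts), rng,
                           achromatic_only=True)
    trace += rf.train(model, fine, epochs=config.finetune_epochs,
                      lr=config.learning_rate / 3, seed=_child_seed(rng),
                      trainable="decoder_only")
    return model, trace


# ---------------------------------------------------------------------------
# Synthetic human observers
# ---------------------------------------------------------------------------

def _simulate_participant_cell(true_cci, comp, trials, restarts, seed):
    positions = {n: sc.COMPETITOR_POSITIONS[n] for n in sca.AXIS_ORDER}
    trial_list = sca.simulate_observer(positions, true_cci / 100.0,
                                       n_trials=trials, seed=seed)
    cm = sca.build_choice_matrix(trial_list)
    scale = sca.fit_mlds(cm, seed=seed, n_restarts=restarts)
    match_lab = sca.map_match_to_lab(scale, comp)
    return sca.compute_cci(match_lab, comp)


def simulate_human_cci_exp1(config: ExperimentConfig) -> pd.DataFrame:
    """Per-participant CCI for every Experiment-1 cell, via the full pipeline."""
    rng = np.random.default_rng(config.seed + 202)
    ills = config.illuminants()
    neutral = ills["neutral"]
    rows = []
    for palette in config.palettes:
        offsets = rng.normal(0.0, config.participant_sd, size=config.n_participants_exp1)
        for p, offset in enumerate(offsets):
            for mech in config.mechanisms:
                delta = 0.0 if mech == "baseline" else config.human_delta[palette][mech]
                for ill_name in sc.ILLUMINANT_NAMES:
                    if ill_name == "neutral":
                        continue
                    comp = sc.make_competitor_set(config.target_reflectance,
                                                  ills[ill_name], neutral)
                    true_cci = max(0.0, config.baseline_cci[palette] + delta
                                   + offset + rng.normal(0.0, config.condition_sd))
                    cci = _simulate_participant_cell(
                        true_cci, comp, config.trials_per_illuminant,
                        config.mlds_restarts, _child_seed(rng))
                    rows.append(dict(agent=f"participant_{palette}_{p}",
                                     kind="human", scene=palette, mechanism=mech,
                                     surround="", illuminant=ill_name, cci=cci,
                                     true_cci=true_cci))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _image_agent_cci(config, agents, mechanisms, surround_reflectance=None,
                     surround_name="", silence_surround=None) -> pd.DataFrame:
    ills = config.illuminants()
    rows = []
    for palette in config.palettes:
        for mech in mechanisms:
            records = sc.generate_experiment_dataset(
                palette=palette, mechanisms=(mech,), illuminants=ills,
                n_locations=config.n_locations, size=config.size,
                target_reflectance=config.target_reflectance,
                surround_reflectance=surround_reflectance,
                seed=config.seed + 11,
            )
            cells = {}
            for r in records:
                cells.setdefault(r.meta["illuminant"], []).append(r)
            for ill_name, recs in cells.items():
                if ill_name == "neutral":
                    continue
                for agent_name, agent in agents.items():
                    cci = mm.captures_to_cci(recs, agent)
                    rows.append(dict(agent=agent_name, kind="image_agent",
                                     scene=palette, mechanism=mech,
                                     surround=surround_name, illuminant=ill_name,
                                     cci=cci, true_cci=np.nan))
    return pd.DataFrame(rows)


def delta_table(cci_df: pd.DataFrame, baseline_label="baseline",
                condition_col="mechanism") -> pd.DataFrame:
    """ΔCCI per (agent, scene, surround, illuminant) against its own baseline."""
    keys = ["agent", "scene", "surround", "illuminant"]
    base = (cci_df[cci_df[condition_col] == baseline_label]
            .set_index(keys)["cci"])
    rows = []
    for _, row in cci_df[cci_df[condition_col] != baseline_label].iterrows():
        k = tuple(row[c] for c in keys)
        if k not in base.index:
            raise KeyError(f"no baseline cell for {k}")
        rows.append({**row, "delta_cci": row["cci"] - base.loc[k]})
    return pd.DataFrame(rows)


def run_experiment1(config: ExperimentConfig, model=None,
                    include_humans: bool = True) -> dict:
    """Full factorial of Experiment 1; returns cci/delta tables and reports.

    The oracle agent scores 100 in every cell and the tristimulus agent
    ~0, bracketing every other agent; ΔCCI is computed per agent against
    its own baseline, and agreement metrics compare each image agent's
    condition vector with the synthetic human pool.
    """
    agents = make_image_agents(config, model=model)
    cci = _image_agent_cci(config, agents, config.mechanisms)
    if include_humans:
        cci = pd.concat([cci, simulate_human_cci_exp1(config)], ignore_index=True)
    delta = delta_table(cci)
    reports = agreement_reports(cci) if include_humans else pd.DataFrame()
    return {"cci": cci, "delta": delta, "agreement": reports}


def run_experiment2(config: ExperimentConfig, model=None,
                    include_humans: bool = True) -> dict:
    """Surround-color experiment: per-surround baseline vs silenced leaf.

    In the baseline the leaf reflects the illuminant naturally; in the
    silenced condition its rendered color is clamped to the neutral
    rendering. Illuminants are labeled Neighboring/Opposing per surround.
    """
    ills = config.illuminants()
    neutral = ills["neutral"]
    surround_refl = sc.make_surround_color_set(ills)
    agents = make_image_agents(config, model=model)
    frames = []
    for s_name in config.surrounds:
        refl = surround_refl[s_name]
        lab = cs.linear_rgb_to_lab(refl * neutral.gain)
        hue = float(np.degrees(np.arctan2(lab[2], lab[1])) % 360.0)
        df = _image_agent_cci(
            config, agents, ("baseline", "local_surround"),
            surround_reflectance=refl, surround_name=s_name)
        df["direction"] = [
            sc.classify_direction(ills[i], hue, neutral) for i in df["illuminant"]]
        frames.append(df)
    cci = pd.concat(frames, ignore_index=True)

    if include_humans:
        rng = np.random.default_rng(config.seed + 303)
        rows = []
        for palette in config.palettes:
            offsets = rng.normal(0.0, config.participant_sd,
                                 size=config.n_participants_exp2)
            for p, offset in enumerate(offsets):
                for s_name in config.surrounds:
                    refl = surround_refl[s_name]
                    lab = cs.linear_rgb_to_lab(refl * neutral.gain)
                    hue = float(np.degrees(np.arctan2(lab[2], lab[1])) % 360.0)
                    for mech in ("baseline", "local_surround"):
                        for ill_name in sc.ILLUMINANT_NAMES:
                            if ill_name == "neutral":
                                continue
                            direction = sc.classify_direction(
                                ills[ill_name], hue, neutral)
                            delta = (0.0 if mech == "baseline"
                                     else config.direction_delta[palette][direction])
                            comp = sc.make_competitor_set(
                                config.target_reflectance, ills[ill_name], neutral)
                            true_cci = max(0.0, config.baseline_cci[palette] + delta
                                           + offset
                                           + rng.normal(0.0, config.condition_sd))
                            cci_val = _simulate_participant_cell(
                                true_cci, comp, config.trials_per_illuminant,
                                config.mlds_restarts, _child_seed(rng))
                            rows.append(dict(
                                agent=f"participant_{palette}_{p}", kind="human",
                                scene=palette, mechanism=mech, surround=s_name,
                                illuminant=ill_name, cci=cci_val,
                                true_cci=true_cci, direction=direction))
        cci = pd.concat([cci, pd.DataFrame(rows)], ignore_index=True)

    delta = delta_table(cci)
    return {"cci": cci, "delta": delta}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _condition_matrix(cci_df, agent_filter):
    """Pivot to (agents, conditions); conditions are (scene, mechanism,
    surround, illuminant) cells present for every selected agent."""
    sub = cci_df[agent_filter(cci_df)].copy()
    sub["condition"] = list(zip(sub["scene"], sub["mechanism"],
                                sub["surround"], sub["illuminant"]))
    return sub.pivot_table(index="agent", columns="condition", values="cci")


def agreement_reports(cci_df: pd.DataFrame) -> pd.DataFrame:
    """Accuracy/bias/normalized error + CCC/LOO/ncCCC per image agent.

    The human matrix pairs the i-th participant of each scene group into
    one pooled row so indoor and outdoor conditions share a participant
    axis (the groups are disjoint in the design).
    """
    humans = _condition_matrix(cci_df, lambda d: d["kind"] == "human")
    # Pool participants across scene groups by index.
    pooled = {}
    for agent in humans.index:
        scene, pid = agent.rsplit("_", 2)[-2:]
        pooled.setdefault(pid, {}).update(humans.loc[agent].dropna().to_dict())
    hdf = pd.DataFrame(pooled).T.sort_index(axis=1)
    hdf = hdf.dropna(axis=1)

    models = _condition_matrix(cci_df, lambda d: d["kind"] == "image_agent")
    models = models[hdf.columns]
    rows = []
    for agent in models.index:
        rep = agr.agreement_report(agent, models.loc[agent].to_numpy(),
                                   hdf.to_numpy())
        rows.append(dict(agent=agent, accuracy=rep.accuracy, bias=rep.bias,
                         normalized_error=rep.normalized_error, ccc=rep.ccc,
                         loo=rep.loo, nccc=rep.nccc))
    return pd.DataFrame(rows)


def make_report(tables: dict) -> str:
    """Human-readable summary: ΔCCI ranking per agent + agreement metrics."""
    delta = tables["delta"]
    lines = ["Mean ΔCCI by mechanism (averaged over scenes and illuminants):"]
    ranking = (delta.groupby(["agent", "mechanism"])["delta_cci"].mean()
               .reset_index().sort_values(["agent", "delta_cci"]))
    for agent, grp in ranking.groupby("agent"):
        parts = ", ".join(f"{r.mechanism}: {r.delta_cci:+.1f}"
                          for r in grp.itertuples())
        lines.append(f"  {agent}: {parts}")
    agree = tables.get("agreement")
    if agree is not None and len(agree):
        lines.append("Model-human agreement:")
        for r in agree.itertuples():
            lines.append(
                f"  {r.agent}: accuracy={r.accuracy:.3f} bias={r.bias:+.1f} "
                f"n.err={r.normalized_error:.3f} ncCCC={r.nccc:.3f}")
    return "\n".join(lines)
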