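"""vegfnet: rule-based model of VEGF-VEGFR2 signaling to ERK1/2 and calcium
and its inhibition by TSP1/CD47.

The package enumerates the receptor reaction network from interaction rules,
compiles it together with a coarse-grained ERK cascade and a calcium module
into one ODE system, and provides parameter fitting (pattern search), PRCC
global sensitivity analysis, and the TSP1 mechanism/therapy simulation
experiments.
"""

__version__ = "0.1.0"

from .rules import (MoleculeType, SpeciesGraph, PatternGraph, Rule, Reaction,
                    ReactionNetwork, Seed, Observable, canonical_label,
                    match_embeddings, generate_network, parse_pattern,
                    parse_species)
from .modelio import ModelDefinition, read_model, write_model, write_sbml
from .params import ParameterSet
from .simulate import (CompiledModel, Protocol, ProtocolEvent, Trajectory,
                       run_protocol, ligand_to_nM, nM_to_unit,
                       density_to_count, count_to_density, vegf_protocol,
                       tsp1_then_vegf_protocol)
from .cascade import CascadeParams, plcg_rate, ras_rate, cascade_rhs
from .calcium import (CalciumParams, CracParams, crac_steady_current,
                      crac_dynamics, calcium_rhs)
from .fitting import FitDataset, FitResult, objective, direct_search, fit
from .sensitivity import (SensitivitySpec, PrccResult, sample_parameters,
                          prcc, run_prcc, rank_report)
from .experiments import (Experiment, ScanSpec, ScanResult,
                          ThresholdCriterion, recovery_threshold,
                          inhibition_threshold)
from .synth import (NoiseModel, PANELS, generate_datasets, make_simulator,
                    recovery_experiment)


def packaged_model():
    """Load the packaged VEGF-TSP1 model definition."""
    from .cli import packaged_model_path
    return read_model(str(packaged_model_path()))
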