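"""End-to-end orchestration: simulate -> extract -> discover -> score ->
filter -> match -> network.

These helpers wire the individual modules together exactly as the CLI does,
and are what the benchmark/acceptance machinery runs. They return a plain
result object so callers can inspect every intermediate product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .genome_ucr import build_ucr_database
from .motif_discovery import DiscoveredMotif, gibbs_discover
from .motif_match import KnownMotif, KnownMotifLibrary, MotifMatch, match_to_known
from .motif_scoring import FilterConfig, MotifScoreReport, filter_cascade, score_motif
from .pssm_core import PSSM, SiteHit, pssm_identity, scan
from .regulatory_network import RegulatoryNetwork, build_network, shared_motifs
from .synthetic_data import SimulationConfig, simulate_dataset


@dataclass
class PipelineResult:
    """Every stage's output for one synthetic benchmark run."""

    ucrs: dict[str, str]
    group: dict[str, str]
    truth: object
    planted: PSSM
    motifs: list[DiscoveredMotif]
    reports: dict[str, MotifScoreReport]
    verdicts: pd.DataFrame
    retained: list[DiscoveredMotif]
    matches: list[MotifMatch]
    network: RegulatoryNetwork
    shared: list[str]

    def best_planted_identity(self) -> float:
        """Highest identity between any discovered motif and the planted PSSM."""
        best = 0.0
        for m in self.motifs:
            ident, _, _ = pssm_identity(m.pssm, self.planted)
            best = max(best, ident)
        return best

    def recovered_motif(self, identity_threshold: float = 70.0) -> DiscoveredMotif | None:
        """The best retained motif at or above the identity threshold, if any."""
        best, best_ident = None, identity_threshold
        for m in self.retained:
            ident, _, _ = pssm_identity(m.pssm, self.planted)
            if ident >= best_ident:
                best, best_ident = m, ident
        return best


def run_benchmark_pipeline(
    config: SimulationConfig,
    width: int = 8,
    discovery_seed: int = 0,
    n_restarts: int = 5,
    iterations: int = 200,
    scan_threshold: float = 85.0,
    filter_config: FilterConfig | None = None,
) -> PipelineResult:
    """Run the full cascade on one simulated dataset.

    Discovery runs on the foreground group's UCRs; scoring uses all UCRs as
    the universe; retained motifs are matched against the simulated library
    (planted + decoys) and their hits across the whole universe feed the
    bipartite network.
    """
    data = simulate_dataset(config)
    records = build_ucr_database(data["annotation"], data["contigs"])
    ucrs = {r.gene_id: r.sequence for r in records}
    truth = data["truth"]
    group = {g: ucrs[g] for g in truth.foreground_genes if g in ucrs}

    motifs = gibbs_discover(
        group, width, n_restarts=n_restarts, iterations=iterations, seed=discovery_seed
    )
    reports = {m.name: score_motif(m, group, ucrs, scan_threshold) for m in motifs}
    retained, verdicts = filter_cascade(motifs, reports, filter_config)

    library = KnownMotifLibrary(
        [KnownMotif(p.name, p.name, (), p) for p in data["library"]]
    )
    matches = match_to_known(retained, library) if len(library) else []

    hits: dict[str, list[SiteHit]] = {
        m.name: [
            h
            for gid, seq in ucrs.items()
            for h in scan(m.pssm, seq, scan_threshold, sequence_id=gid)
        ]
        for m in retained
    }
    network = build_network(retained, hits, truth.category_map, matches)
    shared = shared_motifs(network) if network.motif_nodes() else []
    return PipelineResult(
        ucrs=ucrs,
        group=group,
        truth=truth,
        planted=data["planted"],
        motifs=motifs,
        reports=reports,
        verdicts=verdicts,
        retained=retained,
        matches=matches,
        network=network,
        shared=shared,
    )
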