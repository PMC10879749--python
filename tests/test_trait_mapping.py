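"""Trait-mapping protocol: decision tiers, curation round trip, repository."""

import io

import pytest

from clinannot.trait_mapping import (
    CurationDialectError,
    MappingDecision,
    MappingsRepository,
    RepositoryEntry,
    TraitMapping,
    export_curation,
    feedback_report,
    import_curation,
    map_trait,
    merge_mappings,
)


def repo_with(trait_text, curie, label, active=True):
    return MappingsRepository(
        [RepositoryEntry(trait_text, curie, label, "DONE", active, "2024-01-01")]
    )


class TestMapTrait:
    def test_exact_label_is_automatic(self, ms_store):
        decision = map_trait("Relapsing remitting multiple sclerosis", ms_store)
        assert decision.status == "automatic"
        assert decision.accepted.curie == "EFO:0003929"
        assert decision.accepted.confidence == "AUTO_EXACT_LABEL"

    def test_repository_hit_takes_precedence(self, ms_store):
        repo = repo_with(
            "Relapsing remitting multiple sclerosis", "EFO:0003885",
            "multiple sclerosis",
        )
        decision = map_trait(
            "Relapsing remitting multiple sclerosis", ms_store, repository=repo
        )
        assert decision.status == "automatic"
        assert decision.accepted.confidence == "AUTO_PREVIOUS"
        assert decision.accepted.curie == "EFO:0003885"

    def test_repository_hit_on_obsolete_term_goes_to_curation(self, ms_store):
        repo = repo_with("some old trait", "EFO:0000001", "old multiple sclerosis term")
        decision = map_trait("some old trait", ms_store, repository=repo)
        assert decision.status == "requires_curation"
        # replacement candidate ranked first
        assert decision.candidates[0].curie == "EFO:0003885"

    def test_unique_exact_synonym_is_automatic(self, ms_store):
        decision = map_trait("MS", ms_store)
        assert decision.status == "automatic"
        assert decision.accepted.confidence == "AUTO_EXACT_SYNONYM"
        assert decision.accepted.curie == "EFO:0003885"

    def test_label_plus_synonym_ambiguity_goes_to_curation(self, ms_store):
        decision = map_trait("multiple sclerosis", ms_store)
        assert decision.status == "requires_curation"
        assert [c.curie for c in decision.candidates] == [
            "EFO:0003885",
            "MONDO:0005301",
        ]

    def test_related_synonym_requires_curation(self, ms_store):
        decision = map_trait("disseminated sclerosis", ms_store)
        assert decision.status == "requires_curation"

    def test_gibberish_is_unmapped(self, ms_store):
        assert map_trait("xyzzy frobnication", ms_store).status == "unmapped"

    def test_conservation_over_statuses(self, ms_store):
        texts = [
            "Relapsing remitting multiple sclerosis",
            "MS",
            "multiple sclerosis",
            "disseminated sclerosis",
            "gibberish one",
            "gibberish two",
        ]
        decisions = [map_trait(t, ms_store) for t in texts]
        by_status = {
            s: sum(1 for d in decisions if d.status == s)
            for s in ("automatic", "requires_curation", "unmapped")
        }
        assert sum(by_status.values()) == len(texts)


class TestCurationRoundTrip:
    def _decisions(self, ms_store):
        return [
            map_trait("disseminated sclerosis", ms_store, record_frequency=3),
            map_trait("unknown thing", ms_store, record_frequency=10),
        ]

    def test_export_sorted_by_frequency(self, ms_store):
        sink = io.StringIO()
        export_curation(self._decisions(ms_store), sink)
        lines = sink.getvalue().splitlines()
        assert lines[1].startswith("unknown thing\t10")
        assert lines[2].startswith("disseminated sclerosis\t3")

    def test_candidate_truncation(self, ms_store):
        decision = MappingDecision(
            trait_text="many",
            status="requires_curation",
            candidates=tuple(
                TraitMapping("many", f"u{i}", f"l{i}", "CANDIDATE", "label")
                for i in range(7)
            ),
            record_frequency=1,
        )
        sink = io.StringIO()
        export_curation([decision], sink, n_candidates=5)
        header = sink.getvalue().splitlines()[0].split("\t")
        assert header.count("chosen_curie") == 1
        assert sum(1 for c in header if c.startswith("candidate_")) == 5
        row = sink.getvalue().splitlines()[1].split("\t")
        assert sum(1 for cell in row if cell.startswith("u")) == 5

    def test_automatic_decisions_rejected(self, ms_store):
        decision = map_trait("MS", ms_store)
        with pytest.raises(ValueError):
            export_curation([decision], io.StringIO())

    def _filled_tsv(self, rows):
        header = (
            "trait_text\trecord_frequency\tcandidate_1\tchosen_curie\tstatus\tcomment"
        )
        return io.StringIO("\n".join([header] + rows) + "\n")

    def test_done_row_becomes_curated_mapping(self, ms_store):
        mappings, report = import_curation(
            self._filled_tsv(["trait a\t5\t\tEFO:0003885\tDONE\tok"]), ms_store
        )
        assert len(mappings) == 1
        assert mappings[0].confidence == "CURATED"
        assert mappings[0].curie == "EFO:0003885"
        assert not report.rejected

    def test_done_row_with_obsolete_term_rejected(self, ms_store):
        mappings, report = import_curation(
            self._filled_tsv(["trait a\t5\t\tEFO:0000001\tDONE\t"]), ms_store
        )
        assert mappings == []
        assert report.rejected[0][1] == "obsolete term"

    def test_new_row_routed_to_feedback(self, ms_store):
        mappings, report = import_curation(
            self._filled_tsv(["novel disease\t2\t\t\tNEW\tplease add"]), ms_store
        )
        assert mappings == []
        assert [r["trait_text"] for r in report.feedback_rows] == ["novel disease"]

    def test_missing_columns_fatal(self, ms_store):
        with pytest.raises(CurationDialectError):
            import_curation(io.StringIO("trait_text\tstatus\nfoo\tDONE\n"), ms_store)


class TestMergeMappings:
    def _curated(self, trait, curie, label):
        return TraitMapping(trait, f"http://x/{curie}", label, "CURATED", "curator")

    def test_merge_is_idempotent(self):
        repo = MappingsRepository()
        batch = [self._curated("trait a", "EFO:1", "one")]
        repo, first = merge_mappings(repo, batch)
        repo, second = merge_mappings(repo, batch)
        assert first["added"] == 1
        assert second == {"added": 0, "superseded": 0, "unchanged": 1}

    def test_new_mapping_supersedes_but_retains_old(self):
        repo = MappingsRepository()
        repo, _ = merge_mappings(repo, [self._curated("trait a", "EFO:1", "one")])
        repo, summary = merge_mappings(repo, [self._curated("trait a", "EFO:2", "two")])
        assert summary["superseded"] == 1
        entries = repo.all_entries()
        assert len(entries) == 2
        active = [e for e in entries if e.active]
        assert [e.curie for e in active] == ["http://x/EFO:2"]

    def test_empty_batch_changes_nothing(self):
        repo = MappingsRepository()
        repo, summary = merge_mappings(repo, [])
        assert summary == {"added": 0, "superseded": 0, "unchanged": 0}
        assert len(repo) == 0

    def test_serialization_is_sorted_and_stable(self, tmp_path):
        repo = MappingsRepository()
        merge_mappings(repo, [self._curated("zeta", "EFO:2", "z")])
        merge_mappings(repo, [self._curated("alpha", "EFO:1", "a")])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        repo.save(p1)
        MappingsRepository.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        lines = p1.read_text().splitlines()
        assert lines[1].startswith("alpha") and lines[2].startswith("zeta")

    def test_revalidate_deactivates_stale_entries(self, ms_store):
        repo = repo_with("old trait", "EFO:0000001", "old multiple sclerosis term")
        stale = repo.revalidate(ms_store)
        assert [e.curie for e in stale] == ["EFO:0000001"]
        assert repo.active_entries("old trait") == []


class TestFeedbackReport:
    def test_sections_populated(self, ms_store):
        decisions = [
            MappingDecision(
                trait_text="novel disease",
                status="unmapped",
                trait_xrefs=(("MedGen", "C1234"),),
            )
        ]
        header = (
            "trait_text\trecord_frequency\tcandidate_1\tchosen_curie\tstatus\tcomment"
        )
        tsv = io.StringIO(
            header + "\nnovel disease\t2\t\t\tNEW\t\ntrait a\t5\t\tEFO:0003885\tDONE\t\n"
        )
        _, report = import_curation(tsv, ms_store)
        fb = feedback_report(decisions, report)
        assert fb.ontology_requests[0]["supporting_xrefs"] == "MedGen:C1234"
        assert fb.mapping_assertions == [
            ("trait a", "EFO:0003885", "multiple sclerosis", "DONE")
        ]

    def test_empty_report_writes_headers_only(self, tmp_path, ms_store):
        _, report = import_curation(
            io.StringIO(
                "trait_text\trecord_frequency\tcandidate_1\tchosen_curie\tstatus\tcomment\n"
            ),
            ms_store,
        )
        fb = feedback_report([], report)
        req, asr = tmp_path / "req.tsv", tmp_path / "asr.tsv"
        fb.write(req, asr)
        assert len(req.read_text().splitlines()) == 1
        assert len(asr.read_text().splitlines()) == 1
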