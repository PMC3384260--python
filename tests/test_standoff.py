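"""Standoff I/O: .txt/.a1 reading, dependency dialects, .a2 writing, pipeline."""

import pytest
from click.testing import CliRunner

from biocompose.cli import main as cli_main
from biocompose.fixtures import case
from biocompose.standoff import (
    StandoffError, read_a2, read_dependencies, read_txt_a1,
    run_pipeline, task_label, write_a2,
)
from tests.conftest import run_case


# -----------------------------------------------------------------------------
# .txt + .a1


def _write_doc(tmp_path, text, a1):
    (tmp_path / "d.txt").write_text(text)
    (tmp_path / "d.a1").write_text(a1)
    return tmp_path / "d.txt", tmp_path / "d.a1"


def test_read_txt_a1_parses_entities(tmp_path):
    txt, a1 = _write_doc(tmp_path, "binding of gp41 to receptors.",
                         "T1\tProtein 11 15\tgp41\n")
    doc = read_txt_a1(txt, a1)
    ent, = doc.entities
    assert (ent.id, ent.semantic_type, ent.char_span, ent.text) \
        == ("T1", "Protein", (11, 15), "gp41")
    assert doc.max_t_index == 1


def test_read_txt_a1_empty_a1(tmp_path):
    txt, a1 = _write_doc(tmp_path, "no entities here.", "")
    assert read_txt_a1(txt, a1).entities == []


def test_read_txt_a1_rejects_span_text_mismatch(tmp_path):
    txt, a1 = _write_doc(tmp_path, "binding of gp41.",
                         "T1\tProtein 11 15\tgp99\n")
    with pytest.raises(StandoffError, match="mismatch"):
        read_txt_a1(txt, a1)


# -----------------------------------------------------------------------------
# dependency dialects


RELATION_BLOCK = """\
amod(involvement-3, possible-2)
prep_of(involvement-3, HCMV-5)

nsubj(binds-2, gp41-1)
"""

CONLL_BLOCK = """\
1\tpossible\tpossible\tJJ\t2\tamod
2\tinvolvement\tinvolvement\tNN\t0\troot
3\tHCMV\thcmv\tNN\t2\tprep_of
"""


def test_relation_dialect_parses_labels_and_indices():
    sents = read_dependencies(RELATION_BLOCK.splitlines())
    assert len(sents) == 2
    dep = sents[0].deps[1]
    assert (dep.label, dep.governor, dep.dependent) == ("prep_of", 3, 5)
    # token forms recovered from the mention strings
    assert sents[0].token(3).form == "involvement"


def test_blank_line_separated_blocks_give_sentence_count():
    sents = read_dependencies(RELATION_BLOCK.splitlines())
    assert [s.index for s in sents] == [0, 1]


def test_conll_dialect_round_trips_to_same_structure():
    conll = read_dependencies(CONLL_BLOCK.splitlines())[0]
    rel = read_dependencies(
        ["amod(involvement-2, possible-1)", "prep_of(involvement-2, HCMV-3)"])[0]
    assert {(d.label, d.governor, d.dependent) for d in conll.deps} == \
        {(d.label, d.governor, d.dependent) for d in rel.deps}
    assert conll.token(1).pos == "JJ"       # CoNLL carries POS, relations don't


def test_conll_enhanced_column_adds_extra_heads():
    block = [
        "1\tGATA3\tgata3\tNN\t3\tnsubj\t-",
        "2\tFOXP3\tfoxp3\tNN\t1\tconj_and\t3:nsubj",
        "3\tshowed\tshow\tVBD\t0\troot\t-",
    ]
    sent = read_dependencies(block)[0]
    labels = {(d.label, d.governor, d.dependent) for d in sent.deps}
    assert ("nsubj", 3, 2) in labels and ("conj_and", 1, 2) in labels


def test_malformed_lines_report_line_numbers():
    with pytest.raises(StandoffError, match="line 2"):
        read_dependencies(["nsubj(a-1, b-2)", "nsubj(broken"])


# -----------------------------------------------------------------------------
# .a2 writing


def test_task_label_capitalisation():
    assert task_label("POSITIVE_REGULATION") == "Positive_regulation"
    assert task_label("PROCESS") == "Process"


def test_example_sentence_writes_expected_a2(cases):
    c, res, a2 = run_case("ex14")
    assert a2 == c.expected["a2"]


def test_zero_events_writes_empty_file():
    assert write_a2([], [], 3) == ""


def test_write_read_write_is_a_fixpoint():
    _, res, a2 = run_case("ex7")
    triggers, events, mods = read_a2(a2)
    assert len(triggers) == 2 and len(events) == 2 and len(mods) == 1
    # re-serialising the parsed content reproduces the bytes
    lines = []
    for tid in sorted(triggers, key=lambda t: int(t[1:])):
        etype, start, end, text = triggers[tid]
        lines.append(f"{tid}\t{etype} {start} {end}\t{text}")
    for eid, etype, trig, parts in events:
        body = " ".join(f"{r}:{v}" for r, v in parts)
        lines.append(f"{eid}\t{etype}:{trig}" + (" " + body if body else ""))
    for mid, mtype, target in mods:
        lines.append(f"{mid}\t{mtype} {target}")
    assert "\n".join(lines) + "\n" == a2


def test_write_a2_refuses_dangling_references():
    from biocompose.mapping import EventAnnotation, ModificationAnnotation
    from biocompose.model import SurfaceElement
    trig = SurfaceElement(id="x", tokens=(1,), char_span=(0, 4),
                          sentence_index=0, text="word")
    ghost = EventAnnotation(id="E9", event_type="BINDING", trigger=trig)
    ev = EventAnnotation(id="E1", event_type="REGULATION", trigger=trig,
                         participants=[("Theme", ghost)])
    with pytest.raises(StandoffError, match="E9"):
        write_a2([ev], [], 0)
    mod = ModificationAnnotation(id="M1", mod_type="NEGATION", target=ghost)
    with pytest.raises(StandoffError, match="E9"):
        write_a2([ev, ghost][:1], [mod], 0)


def test_output_is_byte_identical_across_runs():
    a = run_case("ex27")[2]
    b = run_case("ex27")[2]
    assert a == b


# -----------------------------------------------------------------------------
# directory pipeline + CLI


def _conll_lines(sent):
    heads = {}
    for d in sent.deps:
        heads.setdefault(d.dependent, []).append((d.governor, d.label))
    rows = []
    for t in sent.tokens:
        hs = heads.get(t.index, [])
        head, label = hs[0] if hs else (0, "root")
        extra = "|".join(f"{h}:{l}" for h, l in hs[1:]) or "-"
        rows.append(f"{t.index}\t{t.form}\t{t.lemma}\t{t.pos}\t{head}\t{label}\t{extra}")
    return "\n".join(rows)


def _materialise(tmp_path, name):
    c = case(name)
    (tmp_path / f"{name}.txt").write_text(c.doc.text)
    a1 = "".join(
        f"{e.id}\t{e.semantic_type} {e.char_span[0]} {e.char_span[1]}\t{e.text}\n"
        for e in c.doc.entities)
    (tmp_path / f"{name}.a1").write_text(a1)
    dep = "\n\n".join(_conll_lines(s) for s in c.doc.sentences) + "\n"
    (tmp_path / f"{name}.dep").write_text(dep)
    return c


def test_run_pipeline_writes_expected_a2_files(tmp_path):
    indir, outdir = tmp_path / "in", tmp_path / "out"
    indir.mkdir()
    c = _materialise(indir, "ex14")
    results = run_pipeline(indir, outdir)
    assert (outdir / "ex14.a2").read_text() == c.expected["a2"]
    assert "ex14" in results


def test_run_pipeline_missing_resources_fail_before_processing(tmp_path):
    indir = tmp_path / "in"
    indir.mkdir()
    (indir / "doc.txt").write_text("text.")
    with pytest.raises(StandoffError, match="missing"):
        run_pipeline(indir, tmp_path / "out")


def test_cli_end_to_end(tmp_path):
    indir, outdir = tmp_path / "in", tmp_path / "out"
    indir.mkdir()
    c = _materialise(indir, "ex7")
    runner = CliRunner()
    result = runner.invoke(cli_main, [str(indir), "--out", str(outdir),
                                      "--track", "GENIA"])
    assert result.exit_code == 0, result.output
    content = (outdir / "ex7.a2").read_text()
    assert "Negation E1" in content


def test_cli_coref_none_matches_base_on_anaphora_free_fixture(tmp_path):
    indir = tmp_path / "in"
    indir.mkdir()
    _materialise(indir, "ex8")
    runner = CliRunner()
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    assert runner.invoke(cli_main, [str(indir), "--out", str(out_a)]).exit_code == 0
    assert runner.invoke(cli_main, [str(indir), "--out", str(out_b),
                                    "--coref", "none"]).exit_code == 0
    assert (out_a / "ex8.a2").read_text() == (out_b / "ex8.a2").read_text()
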