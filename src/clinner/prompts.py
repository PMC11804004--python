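"""The three zero-shot NER prompt variations and their rendering.

Each variation opens with the same system preamble ("You are an expert in
labeling clinical notes ...") and asks for increasingly structured output:
free text (1), a Python-dictionary-like keyed list (2), and a JSON
``annotations`` array (3).  The clinical case text is substituted for a
sentinel placeholder that cannot collide with document content.
"""

from __future__ import annotations

from dataclasses import dataclass

PLACEHOLDER = "<<<CLINICAL_TEXT>>>"

_PREAMBLE = (
    "You are an expert in labeling clinical notes with mentions of "
    "diseases, symptoms, and medical procedures. "
)

_TEMPLATES = {
    1: _PREAMBLE
    + "Extract the mentions of diseases, symptoms, and medical procedures "
    "from the following clinical note: " + PLACEHOLDER,
    2: _PREAMBLE
    + "Please identify the entities of types [disease, symptom, medical "
    "procedure] in the following clinical document. The output must be "
    "formatted like this: {diseases: [list of diseases], symptoms: "
    "[list of symptoms], medical procedures: [list of medical procedures]} "
    "Document: " + PLACEHOLDER,
    3: _PREAMBLE
    + "Analyze the following clinical note and identify all mentions of "
    "diseases, symptoms, and medical procedures. Provide the annotations "
    "in a structured JSON format. Each identified entity should be "
    "categorized as either a disease, symptom, or medical procedure. "
    'Example JSON format for annotations (Note: Replace "entity1", '
    '"entity2", etc., with actual entity names: { "annotations": [ '
    '{ "entity": "entity1", "category": "disease" }, '
    '{ "entity": "entity2", "category": "symptom" }, '
    '{ "entity": "entity3", "category": "medical procedure" } '
    "... more entities ] }. Now, analyze this clinical note: " + PLACEHOLDER,
}


@dataclass(frozen=True)
class PromptTemplate:
    variation: int
    template: str

    def __post_init__(self) -> None:
        if self.template.count(PLACEHOLDER) != 1:
            raise ValueError("template must contain the placeholder exactly once")


def list_templates() -> list[PromptTemplate]:
    """All three prompt variations, in order."""
    return [PromptTemplate(v, _TEMPLATES[v]) for v in (1, 2, 3)]


def get_template(variation: int) -> PromptTemplate:
    if variation not in _TEMPLATES:
        raise ValueError(f"unknown prompt variation {variation}; expected 1, 2 or 3")
    return PromptTemplate(variation, _TEMPLATES[variation])


def render_prompt(variation: int, doc) -> str:
    """Substitute the clinical case text into the chosen template.

    Pure and deterministic: every byte outside the placeholder is preserved.
    """
    text = doc.text if hasattr(doc, "text") else str(doc)
    if not text:
        raise ValueError("document text must be non-empty")
    return get_template(variation).template.replace(PLACEHOLDER, text)


def export_yaml(path) -> None:
    """Write the templates as YAML (key ``prompt.variation``) for config use."""
    import yaml

    data = {
        "prompt": {
            "placeholder": PLACEHOLDER,
            "variation": {t.variation: t.template for t in list_templates()},
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, allow_unicode=True, sort_keys=True)
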