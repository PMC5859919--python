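"""PubMed query strings used to assemble the informatics-resource set.

Shipped as documented constants for transparency and reuse; executing them
against NCBI E-utilities is left to the user (no network access is assumed
anywhere in this package).
"""

#: MeSH-based query retrieving articles that describe the development or
#: extension of a biomedical software tool or database.
INFORMATICS_RESOURCES_QUERY = (
    '("software"[MeSH Major Topic] OR "databases, factual"[MeSH Major Topic:noexp]'
    ' OR "databases, protein"[MeSH Major Topic:noexp]'
    ' OR "databases, nucleic acid"[MeSH Major Topic:noexp]'
    ' OR "databases, pharmaceutical"[MeSH Major Topic:noexp]'
    ' OR "databases, chemical"[MeSH Major Topic:noexp]'
    ' OR "databases, genetic"[MeSH Major Topic:noexp])'
    ' OR ("software"[MeSH Terms] AND ("databases, factual"[MeSH Terms:noexp]'
    ' OR "databases, protein"[MeSH Terms:noexp]'
    ' OR "databases, nucleic acid"[MeSH Terms:noexp]'
    ' OR "databases, pharmaceutical"[MeSH Terms:noexp]'
    ' OR "databases, chemical"[MeSH Terms:noexp]'
    ' OR "databases, genetic"[MeSH Terms:noexp]))'
    ' OR ("algorithms"[MeSH Terms] AND ("databases, factual"[MeSH Terms:noexp]'
    ' OR "databases, protein"[MeSH Terms:noexp]'
    ' OR "databases, nucleic acid"[MeSH Terms:noexp]'
    ' OR "databases, pharmaceutical"[MeSH Terms:noexp]'
    ' OR "databases, chemical"[MeSH Terms:noexp]'
    ' OR "databases, genetic"[MeSH Terms:noexp]))'
    ' OR ("algorithms"[MeSH Terms] AND "software"[MeSH Terms])'
    ' OR ("computer communication networks"[MeSH Terms]'
    ' AND ("databases, factual"[MeSH Terms:noexp]'
    ' OR "databases, protein"[MeSH Terms:noexp]'
    ' OR "databases, nucleic acid"[MeSH Terms:noexp]'
    ' OR "databases, pharmaceutical"[MeSH Terms:noexp]'
    ' OR "databases, chemical"[MeSH Terms:noexp]'
    ' OR "databases, genetic"[MeSH Terms:noexp]))'
)

#: Subset query: multiple sequence alignment tools published in NAR.
MSA_TOOLS_QUERY = (
    '"multiple sequence alignment" AND SOFTWARE[MAJOR]'
    ' NOT Review[Publication Type] AND "Nucleic acids research"[Journal]'
)

#: Subset query: text mining tools.
TEXT_MINING_TOOLS_QUERY = (
    '"text mining" AND SOFTWARE[MAJOR] NOT Review[Publication Type]'
)
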