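<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="emdbIdType">
    <xs:restriction base="xs:string">
      <xs:pattern value="EMD-[0-9]{4,5}"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="resourceNameType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="EMPIAR"/>
      <xs:enumeration value="PDB"/>
      <xs:enumeration value="PubMed"/>
      <xs:enumeration value="PMC"/>
      <xs:enumeration value="DOI"/>
      <xs:enumeration value="ISSN"/>
      <xs:enumeration value="ORCiD"/>
      <xs:enumeration value="UniProt"/>
      <xs:enumeration value="ComplexPortal"/>
      <xs:enumeration value="ChEMBL"/>
      <xs:enumeration value="ChEBI"/>
      <xs:enumeration value="DrugBank"/>
      <xs:enumeration value="PDBeKB"/>
      <xs:enumeration value="AlphaFoldDB"/>
      <xs:enumeration value="Rfam"/>
      <xs:enumeration value="GO"/>
      <xs:enumeration value="InterPro"/>
      <xs:enumeration value="Pfam"/>
      <xs:enumeration value="CATH"/>
      <xs:enumeration value="SCOP"/>
      <xs:enumeration value="SCOP2"/>
      <xs:enumeration value="SCOP2B"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="provenanceType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="AUTHOR"/>
      <xs:enumeration value="PDBe"/>
      <xs:enumeration value="UNIPROT"/>
      <xs:enumeration value="EUROPEPMC"/>
      <xs:enumeration value="CCD"/>
      <xs:enumeration value="SIFTS"/>
      <xs:enumeration value="AFDB"/>
      <xs:enumeration value="CPX"/>
      <xs:enumeration value="EMICSS"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="levelType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="entry"/>
      <xs:enumeration value="sample"/>
      <xs:enumeration value="sequence"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="emicss">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="resource" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="extra" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="key" type="xs:string" use="required"/>
                        <xs:attribute name="value" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="level" type="levelType" use="required"/>
                  <xs:attribute name="sample_id" type="xs:positiveInteger"/>
                  <xs:attribute name="accession" type="xs:string" use="required"/>
                  <xs:attribute name="provenance" type="provenanceType" use="required"/>
                  <xs:attribute name="score" type="xs:decimal"/>
                  <xs:attribute name="start" type="xs:positiveInteger"/>
                  <xs:attribute name="end" type="xs:positiveInteger"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="resourceNameType" use="required"/>
            <xs:attribute name="version" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="emdb_id" type="emdbIdType" use="required"/>
      <xs:attribute name="schema_version" type="xs:string" use="required"/>
      <xs:attribute name="date" type="xs:date" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
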