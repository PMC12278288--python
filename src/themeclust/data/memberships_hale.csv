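country,cluster
Australia,1
Austria,1
Belgium,1
Canada,1
Cyprus,1
Czechia,1
Denmark,1
Finland,1
France,1
Germany,1
Iceland,1
Ireland,1
Israel,1
Italy,1
Japan,1
Luxembourg,1
Malta,1
Netherlands,1
New Zealand,1
Norway,1
Portugal,1
Slovenia,1
Spain,1
Sweden,1
Switzerland,1
United Kingdom,1
United States,1
Algeria,2
Antigua and Barbuda,2
Argentina,2
Armenia,2
Azerbaijan,2
Bahamas,2
Bahrain,2
Barbados,2
Belarus,2
Belize,2
Bhutan,2
Bolivia,2
Bosnia and Herzegovina,2
Brazil,2
Bulgaria,2
Cambodia,2
Cape Verde,2
Chile,2
China,2
Colombia,2
Costa Rica,2
Croatia,2
Cuba,2
Dominican Republic,2
Ecuador,2
Egypt,2
El Salvador,2
Estonia,2
Fiji,2
Georgia,2
Greece,2
Grenada,2
Guatemala,2
Guyana,2
Honduras,2
Hungary,2
India,2
Indonesia,2
Iran,2
Iraq,2
Jamaica,2
Jordan,2
Kazakhstan,2
Kuwait,2
Kyrgyzstan,2
Latvia,2
Lebanon,2
Lithuania,2
Malaysia,2
Maldives,2
Mauritius,2
Mexico,2
Moldova,2
Mongolia,2
Montenegro,2
Morocco,2
Nicaragua,2
North Macedonia,2
Oman,2
Panama,2
Paraguay,2
Peru,2
Philippines,2
Qatar,2
Romania,2
Russia,2
Saint Lucia,2
Saint Vincent and the Grenadines,2
Samoa,2
Sao Tome and Principe,2
Saudi Arabia,2
Serbia,2
Seychelles,2
Slovakia,2
South Africa,2
Sri Lanka,2
Suriname,2
Tajikistan,2
Thailand,2
Trinidad and Tobago,2
Tunisia,2
Turkmenistan,2
Ukraine,2
United Arab Emirates,2
Uruguay,2
Uzbekistan,2
Venezuela,2
Vietnam,2
Afghanistan,3
Angola,3
Bangladesh,3
Benin,3
Botswana,3
Burkina Faso,3
Burundi,3
Cameroon,3
Central African Republic,3
Chad,3
Comoros,3
Congo,3
Cote d'Ivoire,3
Democratic Republic of Congo,3
Djibouti,3
East Timor,3
Eswatini,3
Ethiopia,3
Gabon,3
Gambia,3
Ghana,3
Guinea,3
Guinea-Bissau,3
Haiti,3
Kenya,3
Kiribati,3
Laos,3
Lesotho,3
Liberia,3
Madagascar,3
Malawi,3
Mali,3
Mauritania,3
Mozambique,3
Myanmar,3
Namibia,3
Nepal,3
Niger,3
Nigeria,3
Pakistan,3
Papua New Guinea,3
Rwanda,3
Senegal,3
Sierra Leone,3
Solomon Islands,3
South Sudan,3
Sudan,3
Tanzania,3
Togo,3
Uganda,3
Vanuatu,3
Zambia,3
Zimbabwe,3
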